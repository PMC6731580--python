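"""Free-text → ontology-term mapping and label resolution.

Query text maps to reference-ontology terms through a static key/value
dictionary — exact matching on normalized keys, with multi-word keys tried
greedily longest-first.  Fuzzy matching, spelling correction and synonym
expansion are deliberately out of scope.

Labels resolve cache-first; a remote Ontology-Lookup-Service-style endpoint
can fill cache misses but is disabled by default so nothing here touches the
network unless asked to.
"""

from __future__ import annotations

import json
import re
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .annotation import OntologyTerm, PrefixRegistry
from .errors import RemoteServiceError, UnresolvedLabelError

DEFAULT_STOPWORDS = frozenset({"of", "in", "the", "a", "an", "to", "from"})

_WORD = re.compile(r"[a-z0-9]+(?:[/'_-][a-z0-9]+)*")


def tokenize(text: str, stopwords: Optional[Iterable[str]] = None) -> list[str]:
    """Lowercase, split on whitespace/punctuation, drop stopwords.

    ``"Flux   OF sodium!"`` → ``["flux", "sodium"]``.
    """
    stop = frozenset(stopwords) if stopwords is not None else DEFAULT_STOPWORDS
    return [w for w in _WORD.findall(text.lower()) if w not in stop]


def _normalize_key(key: str) -> str:
    return " ".join(key.lower().split())


@dataclass
class MappingResult:
    hits: list[tuple[str, OntologyTerm]] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)

    @property
    def terms(self) -> list[OntologyTerm]:
        return [t for _, t in self.hits]


class TermDictionary:
    """Static key → ontology-term dictionary.

    File format: one record per line, ``key<TAB>prefix:id<TAB>uri`` with an
    optional fourth label column; ``#`` starts a comment.  Keys are stored
    lowercase and whitespace-normalized; a key may map to several terms.
    """

    def __init__(self):
        self.entries: dict[str, list[OntologyTerm]] = {}

    @classmethod
    def from_file(
        cls, path: str | Path, registry: Optional[PrefixRegistry] = None
    ) -> "TermDictionary":
        d = cls()
        registry = registry or PrefixRegistry()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.rstrip()
            # full-line comments only: URIs legitimately contain '#'
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'key<TAB>prefix:id<TAB>uri[<TAB>label]'"
                )
            key, curie, uri = parts[0], parts[1], parts[2]
            label = parts[3] if len(parts) > 3 and parts[3] else None
            prefix = curie.split(":", 1)[0].upper()
            if prefix not in ("OPB", "FMA", "CHEBI", "PR", "GO", "UNIPROT"):
                prefix = registry.classify(uri)
            d.add(key, OntologyTerm(uri=uri, prefix=prefix, label=label))
        return d

    def add(self, key: str, term: OntologyTerm) -> None:
        norm = _normalize_key(key)
        if not norm:
            raise ValueError("dictionary key must be non-empty")
        terms = self.entries.setdefault(norm, [])
        if term not in terms:
            terms.append(term)

    def lookup(self, key: str) -> list[OntologyTerm]:
        return list(self.entries.get(_normalize_key(key), []))

    def save(self, path: str | Path) -> None:
        lines = []
        for key in sorted(self.entries):
            for term in self.entries[key]:
                curie = f"{term.prefix}:{term.uri.rsplit('/', 1)[-1].rsplit('#', 1)[-1]}"
                lines.append("\t".join([key, curie, term.uri, term.label or ""]))
        Path(path).write_text("\n".join(lines) + "\n")

    @property
    def max_key_words(self) -> int:
        return max((k.count(" ") + 1 for k in self.entries), default=1)

    def __len__(self) -> int:
        return len(self.entries)


def map_tokens(dictionary: TermDictionary, tokens: Sequence[str]) -> MappingResult:
    """Map tokens to terms by exact normalized-key lookup.

    Multi-word dictionary keys are tried greedily, longest span first, before
    single tokens; every non-stopword token ends up in exactly one of
    ``hits`` or ``unmapped``.
    """
    result = MappingResult()
    i = 0
    max_span = dictionary.max_key_words
    while i < len(tokens):
        matched = False
        for span in range(min(max_span, len(tokens) - i), 0, -1):
            phrase = " ".join(tokens[i : i + span])
            terms = dictionary.lookup(phrase)
            if terms:
                for term in terms:
                    result.hits.append((phrase, term))
                i += span
                matched = True
                break
        if not matched:
            result.unmapped.append(tokens[i])
            i += 1
    return result


class LabelResolver:
    """Cache-first URI → label resolution with optional remote lookup.

    The cache is a flat ``uri<TAB>label`` file.  ``remote_calls`` counts
    lookups that actually went to the wire, so tests can assert the cache
    contract.
    """

    def __init__(
        self,
        cache: Optional[dict[str, str]] = None,
        cache_path: Optional[str | Path] = None,
        remote_url: Optional[str] = None,
        remote_enabled: bool = False,
        timeout: float = 10.0,
    ):
        self.cache: dict[str, str] = dict(cache or {})
        self.cache_path = Path(cache_path) if cache_path else None
        if self.cache_path and self.cache_path.exists():
            self.cache.update(load_label_cache(self.cache_path))
        self.remote_url = remote_url
        self.remote_enabled = remote_enabled
        self.timeout = timeout
        self.remote_calls = 0

    def label_for(self, uri: str) -> str:
        if uri in self.cache:
            return self.cache[uri]
        if not (self.remote_enabled and self.remote_url):
            raise UnresolvedLabelError(uri)
        label = self._fetch_remote(uri)
        self.cache[uri] = label
        if self.cache_path:
            save_label_cache(self.cache, self.cache_path)
        return label

    def _fetch_remote(self, uri: str) -> str:
        self.remote_calls += 1
        quoted = urllib.parse.quote(urllib.parse.quote(uri, safe=""), safe="")
        url = f"{self.remote_url.rstrip('/')}/terms/{quoted}"
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                payload = json.loads(resp.read().decode())
        except Exception as exc:
            raise RemoteServiceError(f"label lookup failed for {uri}: {exc}") from exc
        label = payload.get("label")
        if not label and "_embedded" in payload:  # OLS collection envelope
            terms = payload["_embedded"].get("terms", [])
            label = terms[0].get("label") if terms else None
        if not label:
            raise RemoteServiceError(f"label lookup returned no label for {uri}")
        return label

    def labels(self) -> dict[str, str]:
        return dict(self.cache)


def load_label_cache(path: str | Path) -> dict[str, str]:
    cache: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        uri, _, label = line.partition("\t")
        if uri and label:
            cache[uri] = label
    return cache


def save_label_cache(cache: dict[str, str], path: str | Path) -> None:
    lines = [f"{uri}\t{cache[uri]}" for uri in sorted(cache)]
    Path(path).write_text("\n".join(lines) + "\n")
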