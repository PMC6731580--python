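"""In-memory triple store with conjunctive basic-graph-pattern queries.

A query is a list of triple patterns whose positions are constants or named
wildcards; shared wildcard names denote joins, exactly as in a SPARQL basic
graph pattern.  The full SPARQL grammar is *not* parsed locally — a thin
adapter renders pattern lists as SPARQL SELECT text for a remote read-only
endpoint (the model-repository contract) and both routes return identical
solution sets on the same data.

The join is an ordered nested loop, most selective pattern first.  Corpora
are small (tens of models, thousands of triples); correctness and
deterministic ordering matter more than speed here.
"""

from __future__ import annotations

import json
import re
import urllib.parse
import urllib.request
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .errors import RemoteServiceError
from .rdfio import BNode, IRI, Literal, Node, Triple, _node_key

__all__ = ["Wildcard", "Pattern", "TripleStore", "query_bgp", "SparqlEndpoint",
           "patterns_to_sparql"]


@dataclass(frozen=True)
class Wildcard:
    """A named query variable (``?name`` in SPARQL syntax)."""

    name: str

    def __post_init__(self):
        if not self.name or not re.fullmatch(r"\w+", self.name):
            raise ValueError(f"wildcard name must be a non-empty word: {self.name!r}")

    def __str__(self):
        return f"?{self.name}"


Term = Union[Node, Wildcard]


@dataclass(frozen=True)
class Pattern:
    subject: Term
    predicate: Term
    object: Term

    @property
    def wildcards(self) -> tuple[str, ...]:
        return tuple(
            t.name for t in (self.subject, self.predicate, self.object)
            if isinstance(t, Wildcard)
        )


SolutionRow = dict  # wildcard name → bound Node


class TripleStore:
    """Set-semantics triple store with S/P/O hash indexes."""

    def __init__(self, triples: Iterable[Triple] = ()):
        self._triples: set[Triple] = set()
        self._by_s: dict[Node, set[Triple]] = {}
        self._by_p: dict[Node, set[Triple]] = {}
        self._by_o: dict[Node, set[Triple]] = {}
        self.add_triples(triples)

    def add_triples(self, triples: Iterable[Triple]) -> "TripleStore":
        for t in triples:
            if t in self._triples:
                continue
            self._triples.add(t)
            self._by_s.setdefault(t.subject, set()).add(t)
            self._by_p.setdefault(t.predicate, set()).add(t)
            self._by_o.setdefault(t.object, set()).add(t)
        return self

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, t: Triple) -> bool:
        return t in self._triples

    def __iter__(self):
        return iter(self._triples)

    def candidates(self, pattern: Pattern) -> set[Triple]:
        """Triples matching the constant positions of one pattern."""
        sets = []
        if not isinstance(pattern.subject, Wildcard):
            sets.append(self._by_s.get(pattern.subject, set()))
        if not isinstance(pattern.predicate, Wildcard):
            sets.append(self._by_p.get(pattern.predicate, set()))
        if not isinstance(pattern.object, Wildcard):
            sets.append(self._by_o.get(pattern.object, set()))
        if not sets:
            return set(self._triples)
        result = min(sets, key=len)
        for s in sets:
            if s is not result:
                result = result & s
        return result

    def query(self, patterns: list[Pattern]) -> list[SolutionRow]:
        return query_bgp(self, patterns)


def _bind(pattern: Pattern, triple: Triple, row: SolutionRow) -> Optional[SolutionRow]:
    """Extend ``row`` with the bindings this triple induces, or None on clash."""
    new = row
    for term, value in (
        (pattern.subject, triple.subject),
        (pattern.predicate, triple.predicate),
        (pattern.object, triple.object),
    ):
        if isinstance(term, Wildcard):
            bound = new.get(term.name)
            if bound is None:
                if new is row:
                    new = dict(row)
                new[term.name] = value
            elif bound != value:
                return None
        elif term != value:
            return None
    return new if new is not row else dict(row)


def _substitute(pattern: Pattern, row: SolutionRow) -> Pattern:
    def sub(term: Term) -> Term:
        if isinstance(term, Wildcard) and term.name in row:
            return row[term.name]
        return term

    return Pattern(sub(pattern.subject), sub(pattern.predicate), sub(pattern.object))


def _row_key(row: SolutionRow) -> tuple:
    return tuple(_node_key(row[name]) for name in sorted(row))


def query_bgp(store: TripleStore, patterns: list[Pattern]) -> list[SolutionRow]:
    """All bindings satisfying every pattern simultaneously (conjunctive join).

    Deterministic: rows are sorted by their bound values; insertion and
    pattern order never affect the result.
    """
    if not patterns:
        raise ValueError("query needs at least one pattern")

    def selectivity(p: Pattern, bound: set[str]) -> tuple:
        free = sum(
            1 for t in (p.subject, p.predicate, p.object)
            if isinstance(t, Wildcard) and t.name not in bound
        )
        return (free, len(store.candidates(p)))

    rows: list[SolutionRow] = [{}]
    remaining = list(patterns)
    bound: set[str] = set()
    while remaining:
        remaining.sort(key=lambda p: selectivity(p, bound))
        pattern = remaining.pop(0)
        next_rows: list[SolutionRow] = []
        for row in rows:
            concrete = _substitute(pattern, row)
            for triple in store.candidates(concrete):
                extended = _bind(concrete, triple, row)
                if extended is not None:
                    next_rows.append(extended)
        rows = next_rows
        bound.update(pattern.wildcards)
        if not rows:
            return []
    # distinct + deterministic order
    unique = {}
    for row in rows:
        unique[_row_key(row)] = row
    return [unique[k] for k in sorted(unique)]


# --------------------------------------------------------------------------
# SPARQL SELECT adapter (remote read-only endpoint contract)

def _sparql_term(term: Term) -> str:
    if isinstance(term, Wildcard):
        return f"?{term.name}"
    if isinstance(term, IRI):
        return f"<{term.value}>"
    if isinstance(term, BNode):
        return f"_:{term.id}"
    lit = '"' + term.lexical.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if term.lang:
        return f"{lit}@{term.lang}"
    if term.datatype:
        return f"{lit}^^<{term.datatype}>"
    return lit


def patterns_to_sparql(patterns: list[Pattern]) -> str:
    """Render a pattern list as a SPARQL 1.1 SELECT over one basic graph pattern."""
    names = sorted({w for p in patterns for w in p.wildcards})
    select = " ".join(f"?{n}" for n in names) or "*"
    body = " ".join(
        f"{_sparql_term(p.subject)} {_sparql_term(p.predicate)} "
        f"{_sparql_term(p.object)} ." for p in patterns
    )
    return f"SELECT DISTINCT {select} WHERE {{ {body} }}"


def _node_from_json(binding: dict) -> Node:
    kind = binding["type"]
    if kind == "uri":
        return IRI(binding["value"])
    if kind == "bnode":
        return BNode(binding["value"])
    return Literal(
        binding["value"],
        datatype=binding.get("datatype"),
        lang=binding.get("xml:lang"),
    )


class SparqlEndpoint:
    """Remote SELECT-only endpoint speaking the SPARQL 1.1 JSON results format.

    Satisfies the same query contract as :class:`TripleStore`: ``query(patterns)``
    returns the identical solution set the local join would produce on the
    same data.
    """

    def __init__(self, url: str, timeout: float = 30.0, retries: int = 2):
        self.url = url
        self.timeout = timeout
        self.retries = retries

    def query(self, patterns: list[Pattern]) -> list[SolutionRow]:
        query_text = patterns_to_sparql(patterns)
        data = urllib.parse.urlencode({"query": query_text}).encode()
        req = urllib.request.Request(
            self.url,
            data=data,
            headers={
                "Accept": "application/sparql-results+json",
                "Content-Type": "application/x-www-form-urlencoded",
            },
        )
        last_err: Optional[Exception] = None
        for _ in range(self.retries + 1):
            try:
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    payload = json.loads(resp.read().decode())
                break
            except Exception as exc:  # urllib raises a small zoo of types
                last_err = exc
        else:
            raise RemoteServiceError(f"SPARQL endpoint {self.url}: {last_err}")
        rows = [
            {name: _node_from_json(b) for name, b in binding.items()}
            for binding in payload["results"]["bindings"]
        ]
        unique = {}
        for row in rows:
            unique[_row_key(row)] = row
        return [unique[k] for k in sorted(unique)]
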