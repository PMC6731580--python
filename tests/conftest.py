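"""Shared fixtures: one session-scoped synthetic workspace plus oracles."""

from __future__ import annotations

import itertools
import random
from pathlib import Path

import pytest

from modeldiscovery import load_corpus
from modeldiscovery.annotation import PrefixRegistry
from modeldiscovery.fixtures import CorpusSpec, generate_corpus
from modeldiscovery.rdfio import BNode, IRI, Literal, Triple
from modeldiscovery.store import Pattern, Wildcard
from modeldiscovery.terms import TermDictionary, load_label_cache


@pytest.fixture(scope="session")
def workspace(tmp_path_factory):
    """Generated epithelial-mini workspace: (generated, directory)."""
    out = tmp_path_factory.mktemp("epithelial_mini")
    generated = generate_corpus(CorpusSpec(), out)
    return generated, out


@pytest.fixture(scope="session")
def ingested(workspace):
    """(generated, corpus, models, dictionary, labels) from the workspace on disk."""
    generated, out = workspace
    registry = PrefixRegistry.from_file(out / "prefixes.tsv")
    corpus, models = load_corpus(out, registry=registry)
    dictionary = TermDictionary.from_file(out / "dictionary.tsv", registry)
    labels = load_label_cache(out / "labels.tsv")
    return generated, corpus, models, dictionary, labels


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_bgp(triples, patterns):
    """Nested-loop enumeration over every combination of bindings."""
    triples = list(triples)
    rows = []
    for combo in itertools.product(triples, repeat=len(patterns)):
        binding = {}
        ok = True
        for pattern, triple in zip(patterns, combo):
            for term, value in (
                (pattern.subject, triple.subject),
                (pattern.predicate, triple.predicate),
                (pattern.object, triple.object),
            ):
                if isinstance(term, Wildcard):
                    if term.name in binding and binding[term.name] != value:
                        ok = False
                        break
                    binding[term.name] = value
                elif term != value:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            rows.append(binding)
    seen = set()
    unique = []
    for row in rows:
        key = tuple(sorted((k, repr(v)) for k, v in row.items()))
        if key not in seen:
            seen.add(key)
            unique.append(row)
    return unique


def exhaustive_align_score(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    """Maximum global alignment score by plain recursion (tiny inputs only)."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    sub = match if a[0] == b[0] else mismatch
    return max(
        sub + exhaustive_align_score(a[1:], b[1:], match, mismatch, gap),
        gap + exhaustive_align_score(a[1:], b, match, mismatch, gap),
        gap + exhaustive_align_score(a, b[1:], match, mismatch, gap),
    )


def random_graph(rng: random.Random, n_triples: int) -> list[Triple]:
    """Small random RDF graph over a limited vocabulary (forces joins)."""
    subjects = [IRI(f"urn:s{i}") for i in range(6)] + [BNode(f"b{i}") for i in range(2)]
    predicates = [IRI(f"urn:p{i}") for i in range(4)]
    objects = subjects + [Literal(str(i)) for i in range(4)]
    triples = set()
    while len(triples) < n_triples:
        triples.add(
            Triple(rng.choice(subjects), rng.choice(predicates), rng.choice(objects))
        )
    return list(triples)


def random_patterns(rng: random.Random, n_patterns: int = 3) -> list[Pattern]:
    wildcards = [Wildcard("x"), Wildcard("y"), Wildcard("z")]
    constants = (
        [IRI(f"urn:s{i}") for i in range(6)]
        + [IRI(f"urn:p{i}") for i in range(4)]
        + [Literal(str(i)) for i in range(4)]
    )

    def term(position):
        if rng.random() < 0.5:
            return rng.choice(wildcards)
        return rng.choice(constants)

    patterns = []
    for _ in range(n_patterns):
        p = Pattern(term("s"), term("p"), term("o"))
        if not p.wildcards:  # keep joins interesting
            p = Pattern(rng.choice(wildcards), p.predicate, p.object)
        patterns.append(p)
    return patterns
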