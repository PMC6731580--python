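"""Free-text model discovery over an annotated corpus.

A query like ``"flux of sodium"`` is decomposed into ontology terms via the
static dictionary, then executed as cascading basic-graph-pattern queries
over the corpus triple store: the first stage explores annotation slots
(physical property, chemical, anatomical location, protein mediator) and
model names; later stages enrich surviving entities with protein accessions
and species/gene metadata rather than filtering them.  An entity matching
both the property and the chemical ("sodium" + "flux") outranks one matching
the chemical alone, so directly relevant variables surface first while other
sodium-related resources still appear lower down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .annotation import (
    AnnotatedCorpus,
    CompositeAnnotation,
    ModelEntity,
    OntologyTerm,
    render_description,
)
from .codec import DEFAULT_VOCABULARY, encode_annotations
from .errors import UnresolvedLabelError
from .rdfio import IRI, Literal
from .store import Pattern, TripleStore, Wildcard
from .terms import MappingResult, TermDictionary, map_tokens, tokenize

SLOTS = ("property", "chemical", "location", "mediator", "model_name")

#: artifact-defined slot weights; the qualitative ordering constraint is that
#: property+chemical beats any single slot.
DEFAULT_WEIGHTS = {
    "property": 0.35,
    "chemical": 0.35,
    "location": 0.15,
    "mediator": 0.10,
    "model_name": 0.05,
}


def validate_weights(weights: Mapping[str, float]) -> dict[str, float]:
    if set(weights) != set(SLOTS):
        raise ValueError(f"weights must cover exactly the slots {SLOTS}")
    if any(w <= 0 for w in weights.values()):
        raise ValueError("slot weights must be positive")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"slot weights must sum to 1, got {total}")
    return dict(weights)


def score_entity(
    matched_slots: Sequence[str], weights: Optional[Mapping[str, float]] = None
) -> float:
    """Σ slot-weight × [slot matched]; 0 when nothing matched."""
    w = validate_weights(weights or DEFAULT_WEIGHTS)
    return sum(w[s] for s in set(matched_slots))


def accession_from_uri(uri: str) -> str:
    """Protein accession = final path segment of a mediator term URI."""
    return uri.rstrip("/#").rsplit("/", 1)[-1].rsplit("#", 1)[-1]


@dataclass
class SearchResult:
    entity: ModelEntity
    model_name: str
    score: float
    matched_terms: list[tuple[OntologyTerm, str]]
    description: str
    protein: Optional[str] = None
    species: Optional[str] = None
    gene: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "entity": self.entity.uri,
            "model": self.model_name,
            "score": round(self.score, 6),
            "matched": [
                {"slot": slot, "term": term.uri} for term, slot in self.matched_terms
            ],
            "description": self.description,
            "protein": self.protein,
            "species": self.species,
            "gene": self.gene,
        }


@dataclass
class RankedResults:
    query: str
    results: list[SearchResult] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)


class CorpusStore:
    """An annotated corpus indexed as RDF triples, queryable as BGPs."""

    def __init__(self, corpus: AnnotatedCorpus, vocab: Optional[dict] = None):
        self.corpus = corpus
        self.vocab = vocab or DEFAULT_VOCABULARY
        self.store = TripleStore(encode_annotations(corpus, self.vocab))

    # -- cascading query stages ------------------------------------------
    def entities_matching_term(self, term: OntologyTerm) -> dict[str, str]:
        """Stage-1 call: entity URI → slot for one mapped term."""
        v = self.vocab
        found: dict[str, str] = {}
        direct = [("property", v["property"]), ("chemical", v["chemical"]),
                  ("mediator", v["mediator"])]
        for slot, pred in direct:
            for row in self.store.query(
                [Pattern(Wildcard("e"), IRI(pred), IRI(term.uri))]
            ):
                found[row["e"].value] = slot
        for pred in (v["source"], v["sink"], v["located_in"]):
            rows = self.store.query(
                [
                    Pattern(Wildcard("e"), IRI(pred), Wildcard("b")),
                    Pattern(Wildcard("b"), IRI(v["reference_term"]), IRI(term.uri)),
                ]
            )
            for row in rows:
                found.setdefault(row["e"].value, "location")
        return found

    def entities_of_models_named(self, token: str) -> list[str]:
        """Stage-1 call: entities of models whose name contains the token."""
        token = token.lower()
        hits = []
        for model in self.corpus.models.values():
            if token in model.name.lower():
                hits.extend(
                    uri for uri, e in self.corpus.entities.items()
                    if e.model_file == model.file
                )
        return hits

    def protein_for(self, entity_uri: str) -> Optional[str]:
        """Stage-2 call: protein accession via the mediator participant."""
        rows = self.store.query(
            [Pattern(IRI(entity_uri), IRI(self.vocab["mediator"]), Wildcard("m"))]
        )
        for row in rows:
            if isinstance(row["m"], IRI):
                return accession_from_uri(row["m"].value)
        return None

    def species_gene_for(self, entity_uri: str) -> tuple[Optional[str], Optional[str]]:
        """Stage-3 call: species and gene literals for an entity."""
        out = []
        for key in ("species", "gene"):
            rows = self.store.query(
                [Pattern(IRI(entity_uri), IRI(self.vocab[key]), Wildcard("x"))]
            )
            out.append(
                next((r["x"].lexical for r in rows if isinstance(r["x"], Literal)), None)
            )
        return out[0], out[1]


def _describe(
    annotation: CompositeAnnotation, labels: Optional[Mapping[str, str]]
) -> str:
    try:
        return render_description(annotation, labels)
    except UnresolvedLabelError:
        return ""


def search(
    corpus_store: CorpusStore | AnnotatedCorpus,
    dictionary: TermDictionary,
    query_text: str,
    weights: Optional[Mapping[str, float]] = None,
    labels: Optional[Mapping[str, str]] = None,
) -> RankedResults:
    """Rank annotated model entities against a free-text query.

    Deterministic: scores sort non-increasing; ties break on variable-level
    before component-level entities, then model name, then entity URI.
    """
    if isinstance(corpus_store, AnnotatedCorpus):
        corpus_store = CorpusStore(corpus_store)
    corpus = corpus_store.corpus
    w = validate_weights(weights or DEFAULT_WEIGHTS)

    tokens = tokenize(query_text)
    mapping: MappingResult = map_tokens(dictionary, tokens)

    matched: dict[str, list[tuple[OntologyTerm, str]]] = {}
    for token, term in mapping.hits:
        for uri, slot in corpus_store.entities_matching_term(term).items():
            matched.setdefault(uri, []).append((term, slot))
    for token in tokens:
        for uri in corpus_store.entities_of_models_named(token):
            slots = matched.setdefault(uri, [])
            name_term = None  # model-name matches carry no ontology term
            if all(slot != "model_name" for _, slot in slots):
                slots.append((name_term, "model_name"))

    results: list[SearchResult] = []
    for uri, term_slots in matched.items():
        anns = corpus.annotations_for(uri)
        if not anns:
            continue  # unannotated entities carry no biological meaning to show
        slots = {slot for _, slot in term_slots}
        score = score_entity(sorted(slots), w)
        if score <= 0:
            continue
        protein = corpus_store.protein_for(uri)
        species, gene = corpus_store.species_gene_for(uri)
        entity = corpus.entities[uri]
        results.append(
            SearchResult(
                entity=entity,
                model_name=corpus.model_of(uri).name,
                score=score,
                matched_terms=[(t, s) for t, s in term_slots if t is not None],
                description=_describe(anns[0], labels),
                protein=protein,
                species=species,
                gene=gene,
            )
        )

    results.sort(
        key=lambda r: (
            -r.score,
            r.entity.variable is None,  # variable-level entities first on ties
            r.model_name,
            r.entity.uri,
        )
    )
    return RankedResults(query=query_text, results=results, unmapped=mapping.unmapped)
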