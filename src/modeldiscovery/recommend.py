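"""Overview cards and similar-model recommendations.

Selecting a model entity yields (1) an overview card — anatomical location,
biological meaning, species, gene, protein — assembled purely from the
corpus annotations, and (2) a ranked list of similar or alternative models.
Candidates share at least one anatomical term with the selected entity
(intersection over the located-in/source/sink chains, so apical and
basolateral transporter populations fall into distinct groups by shared-term
count).  Among candidates whose mediators carry protein accessions, a
percent-identity matrix including the selected protein orders them by
descending sequence similarity; location-only candidates follow, ordered by
how many anatomical terms they share.  Two alternative groups are reported
alongside: the same protein modelled in other species, and organ models from
associated workspaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .annotation import (
    AnnotatedCorpus,
    CompositeAnnotation,
    ModelEntity,
    render_description,
)
from .errors import ModelDiscoveryError, NotFoundError, UnresolvedLabelError
from .search import accession_from_uri
from .seqsim import ProteinRecord, Scoring, DEFAULT_SCORING, SequenceSource, similarity_matrix

#: weight of the shared-location fraction for candidates without sequences;
#: sequence-based candidates always sort ahead of location-only ones.
LOCATION_RANK_WEIGHT = 0.5


@dataclass
class OverviewCard:
    entity: ModelEntity
    anatomical_location: list[str]
    biological_meaning: str
    species: Optional[str] = None
    gene: Optional[str] = None
    protein_name: Optional[str] = None
    protein_accession: Optional[str] = None
    mediator_info: Optional[tuple[str, str]] = None  # (name, uri)
    model_link: str = ""

    def as_dict(self) -> dict:
        return {
            "entity": self.entity.uri,
            "anatomical_location": self.anatomical_location,
            "biological_meaning": self.biological_meaning,
            "species": self.species,
            "gene": self.gene,
            "protein_name": self.protein_name,
            "protein_accession": self.protein_accession,
            "mediator_info": list(self.mediator_info) if self.mediator_info else None,
            "model_link": self.model_link,
        }


@dataclass
class Recommendation:
    candidate: ModelEntity
    model_name: str
    basis: frozenset[str]
    rank_score: float
    similarity: Optional[float] = None
    shared_locations: int = 0

    def as_dict(self) -> dict:
        return {
            "candidate": self.candidate.uri,
            "model": self.model_name,
            "basis": sorted(self.basis),
            "rank_score": round(self.rank_score, 6),
            "similarity": self.similarity,
            "shared_locations": self.shared_locations,
        }


def _primary_annotation(
    corpus: AnnotatedCorpus, entity_uri: str
) -> CompositeAnnotation:
    anns = corpus.annotations_for(entity_uri)
    if not anns:
        raise NotFoundError(f"entity has no annotation: {entity_uri}")
    return anns[0]


def _safe_description(ann: CompositeAnnotation, labels) -> str:
    try:
        return render_description(ann, labels)
    except UnresolvedLabelError:
        return ""


def _term_label(term, labels) -> str:
    if term.label:
        return term.label
    if labels and term.uri in labels:
        return labels[term.uri]
    return term.uri


def overview(
    corpus: AnnotatedCorpus,
    entity_uri: str,
    labels: Optional[Mapping[str, str]] = None,
) -> OverviewCard:
    """Overview card for a selected entity, from corpus annotations alone."""
    if entity_uri not in corpus.entities:
        raise NotFoundError(f"unknown entity: {entity_uri}")
    ann = _primary_annotation(corpus, entity_uri)
    entity = corpus.entities[entity_uri]
    mediator = ann.mediator
    return OverviewCard(
        entity=entity,
        anatomical_location=[
            _term_label(t, labels)
            for t in (*ann.located_in, *ann.source_location, *ann.sink_location)
        ],
        biological_meaning=_safe_description(ann, labels),
        species=ann.species,
        gene=ann.gene,
        protein_name=_term_label(mediator, labels) if mediator else None,
        protein_accession=accession_from_uri(mediator.uri) if mediator else None,
        mediator_info=(
            (_term_label(mediator, labels), mediator.uri) if mediator else None
        ),
        model_link=entity.model_file,
    )


def recommend(
    corpus: AnnotatedCorpus,
    entity_uri: str,
    seq_source: Optional[SequenceSource] = None,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[Recommendation]:
    """Ranked similar/alternative model entities for a selected entity.

    Deterministic for a fixed corpus and sequence source; the selected entity
    itself is never recommended, and removing one candidate never reorders
    the others (the ordering is a pure sort key per candidate).
    """
    if entity_uri not in corpus.entities:
        raise NotFoundError(f"unknown entity: {entity_uri}")
    selected_ann = _primary_annotation(corpus, entity_uri)
    selected_entity = corpus.entities[entity_uri]
    selected_locs = selected_ann.location_terms
    selected_acc = (
        accession_from_uri(selected_ann.mediator.uri) if selected_ann.mediator else None
    )

    # candidate pool: annotated entities of *other* models sharing a location
    candidates: list[tuple[str, CompositeAnnotation, int]] = []
    for ann in corpus.annotations:
        uri = ann.target.uri
        if uri == entity_uri or ann.target.model_file == selected_entity.model_file:
            continue
        shared = len(selected_locs & ann.location_terms)
        if shared:
            candidates.append((uri, ann, shared))

    # sequence-similarity group
    accession_of: dict[str, str] = {}
    for uri, ann, _ in candidates:
        if ann.mediator:
            accession_of[uri] = accession_from_uri(ann.mediator.uri)
    similarities: dict[str, float] = {}
    if selected_acc and seq_source and accession_of:
        records: dict[str, ProteinRecord] = {}
        try:
            records[selected_acc] = seq_source.fetch(selected_acc)
        except ModelDiscoveryError as exc:
            warnings.warn(f"selected protein {selected_acc}: {exc}", stacklevel=2)
        if selected_acc in records:
            fetched: dict[str, ProteinRecord] = {}
            for uri, acc in accession_of.items():
                if acc == selected_acc:
                    continue
                try:
                    fetched[acc] = seq_source.fetch(acc)
                except ModelDiscoveryError as exc:
                    # degrade to location-only basis
                    warnings.warn(f"candidate protein {acc}: {exc}", stacklevel=2)
            if fetched:
                matrix = similarity_matrix(
                    [records[selected_acc]]
                    + [fetched[a] for a in sorted(fetched)],
                    scoring,
                )
                row = matrix.row(selected_acc)
                for uri, acc in accession_of.items():
                    if acc in row and acc != selected_acc:
                        similarities[uri] = row[acc]

    recs: list[Recommendation] = []
    n_sel = max(len(selected_locs), 1)
    for uri, ann, shared in candidates:
        basis = {"same_location"}
        sim = similarities.get(uri)
        if sim is not None:
            basis.add("sequence_similarity")
        if (
            ann.mediator
            and selected_acc
            and accession_of.get(uri) == selected_acc
            and ann.species
            and selected_ann.species
            and ann.species.lower() != selected_ann.species.lower()
        ):
            basis.add("same_protein_other_species")
        cand_model = corpus.models[ann.target.model_file]
        sel_model = corpus.models[selected_entity.model_file]
        if (
            cand_model.workspace
            and sel_model.workspace
            and cand_model.workspace == sel_model.workspace
            and cand_model.organ
        ):
            basis.add("same_workspace_organ")
        rank = (
            sim / 100.0
            if sim is not None
            else LOCATION_RANK_WEIGHT * (shared / n_sel)
        )
        recs.append(
            Recommendation(
                candidate=ann.target,
                model_name=cand_model.name,
                basis=frozenset(basis),
                rank_score=rank,
                similarity=sim,
                shared_locations=shared,
            )
        )

    recs.sort(
        key=lambda r: (
            "sequence_similarity" not in r.basis,  # sequence group first
            -(r.similarity if r.similarity is not None else 0.0),
            -r.shared_locations,
            r.candidate.uri,
        )
    )
    return recs
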