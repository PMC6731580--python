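"""Composite-annotation data model and the entity URI scheme.

A *composite annotation* describes the biological meaning of one variable (or
component) of a biosimulation model by combining terms from several reference
ontologies: a biophysical property (OPB), a chemical species (ChEBI), chains of
anatomical locations (FMA) and an optional protein mediator (PR / UniProt).
Model entities are addressed with URIs of the form ``file#component.variable``,
mirroring how annotations are anchored to CellML metadata identifiers inside a
model repository workspace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import (
    AnnotationInvariantError,
    InvalidEntityError,
    MalformedUriError,
    UnresolvedLabelError,
)

__all__ = [
    "OntologyTerm",
    "ModelEntity",
    "CompositeAnnotation",
    "ModelDescriptor",
    "AnnotatedCorpus",
    "PrefixRegistry",
    "construct_entity_uri",
    "parse_entity_uri",
    "render_description",
]

KNOWN_PREFIXES = ("OPB", "FMA", "CHEBI", "PR", "GO", "UNIPROT", "OTHER")

#: built-in URI stems for the reference ontologies; a registry file can extend
#: or override these (fixture corpora register their own example-namespace stems).
DEFAULT_PREFIX_STEMS = {
    "http://identifiers.org/opb/": "OPB",
    "http://bhi.washington.edu/OPB#": "OPB",
    "http://purl.org/obo/owl/FMA#": "FMA",
    "http://purl.obolibrary.org/obo/FMA_": "FMA",
    "http://purl.obolibrary.org/obo/CHEBI_": "CHEBI",
    "http://identifiers.org/chebi/CHEBI:": "CHEBI",
    "http://purl.obolibrary.org/obo/PR_": "PR",
    "http://purl.obolibrary.org/obo/GO_": "GO",
    "http://identifiers.org/uniprot/": "UNIPROT",
    "http://purl.uniprot.org/uniprot/": "UNIPROT",
}

_ABSOLUTE_IRI = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*:")


class PrefixRegistry:
    """Maps ontology URI stems to short prefixes (OPB, FMA, CHEBI, ...).

    The registry file is flat text, one ``prefix<TAB>uri-stem`` record per
    line; ``#`` starts a comment.  Unknown stems classify as ``OTHER``.
    """

    def __init__(self, stems: Optional[Mapping[str, str]] = None):
        self._stems: dict[str, str] = dict(DEFAULT_PREFIX_STEMS)
        if stems:
            self._stems.update(stems)

    @classmethod
    def from_file(cls, path: str | Path) -> "PrefixRegistry":
        stems: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            # full-line comments only: URI stems legitimately end in '#'
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'prefix<TAB>stem'")
            prefix, stem = parts[0].strip().upper(), parts[1].strip()
            stems[stem] = prefix
        return cls(stems)

    def add(self, stem: str, prefix: str) -> None:
        self._stems[stem] = prefix.upper()

    def classify(self, uri: str) -> str:
        # longest stem wins so nested namespaces resolve specifically
        best, best_len = "OTHER", -1
        for stem, prefix in self._stems.items():
            if uri.startswith(stem) and len(stem) > best_len:
                best, best_len = prefix, len(stem)
        return best


@dataclass(frozen=True)
class OntologyTerm:
    """A reference-ontology concept: an absolute IRI, its prefix, and a label.

    Equality and hashing are by URI alone — two terms with different cached
    labels but the same IRI denote the same concept.
    """

    uri: str
    prefix: str = "OTHER"
    label: Optional[str] = None

    def __post_init__(self):
        uri = self.uri.strip()
        if not uri or not _ABSOLUTE_IRI.match(uri):
            raise ValueError(f"not an absolute IRI: {self.uri!r}")
        object.__setattr__(self, "uri", uri)
        if self.prefix not in KNOWN_PREFIXES:
            raise ValueError(f"unknown ontology prefix: {self.prefix!r}")

    @classmethod
    def from_uri(
        cls,
        uri: str,
        registry: Optional[PrefixRegistry] = None,
        label: Optional[str] = None,
    ) -> "OntologyTerm":
        registry = registry or PrefixRegistry()
        return cls(uri=uri, prefix=registry.classify(uri.strip()), label=label)

    def __eq__(self, other):
        if not isinstance(other, OntologyTerm):
            return NotImplemented
        return self.uri == other.uri

    def __hash__(self):
        return hash(self.uri)


@dataclass(frozen=True)
class ModelEntity:
    """An addressable variable or component of a CellML file.

    ``variable`` is ``None`` for component-level entities.  The canonical URI
    is ``model_file#component.variable`` (or ``model_file#component``); the
    fragment doubles as the document-unique metadata identifier unless one is
    given explicitly.
    """

    model_file: str
    component: str
    variable: Optional[str] = None
    metadata_id: Optional[str] = None

    def __post_init__(self):
        if not self.model_file:
            raise InvalidEntityError("entity has empty model file")
        if not self.component:
            raise InvalidEntityError("entity has empty component")
        if self.metadata_id is None:
            object.__setattr__(self, "metadata_id", self.fragment)

    @property
    def fragment(self) -> str:
        if self.variable:
            return f"{self.component}.{self.variable}"
        return self.component

    @property
    def uri(self) -> str:
        return construct_entity_uri(self)

    def __str__(self) -> str:
        return self.uri


def construct_entity_uri(entity: ModelEntity) -> str:
    """Canonical URI ``file#component.variable`` (variable omitted if absent)."""
    if not entity.model_file or not entity.component:
        raise InvalidEntityError("entity needs a model file and a component")
    return f"{entity.model_file}#{entity.fragment}"


def parse_entity_uri(uri: str) -> ModelEntity:
    """Inverse of :func:`construct_entity_uri`.

    The file part is everything before the single ``#``; within the fragment
    the FIRST ``.`` separates component from variable (component identifiers
    may not contain dots; variable names may).
    """
    if uri.count("#") != 1:
        raise MalformedUriError(f"entity URI needs exactly one '#': {uri!r}")
    model_file, fragment = uri.split("#")
    if not fragment:
        raise MalformedUriError(f"entity URI has an empty fragment: {uri!r}")
    if not model_file:
        raise MalformedUriError(f"entity URI has an empty file part: {uri!r}")
    if "." in fragment:
        component, variable = fragment.split(".", 1)
    else:
        component, variable = fragment, None
    if not component:
        raise MalformedUriError(f"entity URI has an empty component: {uri!r}")
    return ModelEntity(model_file=model_file, component=component, variable=variable)


@dataclass(frozen=True)
class CompositeAnnotation:
    """One composite annotation bound to one model entity.

    ``property`` (OPB) is mandatory.  Process-type annotations (fluxes) carry
    ``source_location``/``sink_location`` chains; state-type annotations
    (concentrations, amounts) carry ``located_in``.  Location chains are
    ordered most-specific-first and may not repeat a term.
    """

    target: ModelEntity
    property: OntologyTerm
    chemical: Optional[OntologyTerm] = None
    source_location: tuple[OntologyTerm, ...] = ()
    sink_location: tuple[OntologyTerm, ...] = ()
    located_in: tuple[OntologyTerm, ...] = ()
    mediator: Optional[OntologyTerm] = None
    species: Optional[str] = None
    gene: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "source_location", tuple(self.source_location))
        object.__setattr__(self, "sink_location", tuple(self.sink_location))
        object.__setattr__(self, "located_in", tuple(self.located_in))
        for name in ("source_location", "sink_location", "located_in"):
            chain = getattr(self, name)
            if len(set(chain)) != len(chain):
                raise AnnotationInvariantError(
                    f"{self.target}: duplicate term in {name} chain"
                )
        if self.is_process and self.located_in:
            raise AnnotationInvariantError(
                f"{self.target}: process annotation may not use located_in"
            )

    @property
    def is_process(self) -> bool:
        """True when the annotation describes a process (has source or sink)."""
        return bool(self.source_location or self.sink_location)

    @property
    def location_terms(self) -> frozenset[OntologyTerm]:
        """All anatomical terms across the three chains (for location matching)."""
        return frozenset(self.source_location + self.sink_location + self.located_in)

    @property
    def all_terms(self) -> frozenset[OntologyTerm]:
        terms = {self.property}
        if self.chemical:
            terms.add(self.chemical)
        if self.mediator:
            terms.add(self.mediator)
        return frozenset(terms) | self.location_terms


def _label(term: OntologyTerm, labels: Optional[Mapping[str, str]]) -> str:
    if term.label:
        return term.label
    if labels and term.uri in labels:
        return labels[term.uri]
    raise UnresolvedLabelError(term.uri)


def _chain_text(chain: Sequence[OntologyTerm], labels) -> str:
    # most specific first: "cytosol of epithelial cell"
    return " of ".join(_label(t, labels) for t in chain)


def render_description(
    annotation: CompositeAnnotation,
    labels: Optional[Mapping[str, str]] = None,
) -> str:
    """Human-readable text for a composite annotation.

    Process form: ``<chemical> <property> from <source> to <sink> via
    <mediator>``; state form: ``<chemical> <property> in <location>``.
    Absent slots collapse without leaving dangling prepositions, e.g. an
    unmediated flux renders as ``sodium flux from lumen to cytosol``.
    """
    parts: list[str] = []
    if annotation.chemical:
        parts.append(_label(annotation.chemical, labels))
    parts.append(_label(annotation.property, labels))
    if annotation.is_process:
        if annotation.source_location:
            parts.append("from " + _chain_text(annotation.source_location, labels))
        if annotation.sink_location:
            parts.append("to " + _chain_text(annotation.sink_location, labels))
        if annotation.mediator:
            parts.append("via " + _label(annotation.mediator, labels))
    else:
        if annotation.located_in:
            parts.append("in " + _chain_text(annotation.located_in, labels))
        if annotation.mediator:
            parts.append("via " + _label(annotation.mediator, labels))
    return " ".join(parts)


@dataclass(frozen=True)
class ModelDescriptor:
    """A model in the corpus: its file, display name and optional tags."""

    file: str
    name: str
    workspace: Optional[str] = None
    organ: Optional[str] = None


class AnnotatedCorpus:
    """A set of models plus their composite annotations, with lookup indexes.

    The indexes (entity URI → annotations, term URI → entity URIs) are derived
    data: rebuilding them from the annotation set yields identical content.
    """

    def __init__(
        self,
        models: Iterable[ModelDescriptor] = (),
        annotations: Iterable[CompositeAnnotation] = (),
        entities: Iterable[ModelEntity] = (),
    ):
        self.models: dict[str, ModelDescriptor] = {}
        self.annotations: list[CompositeAnnotation] = []
        self.entities: dict[str, ModelEntity] = {}
        self._by_entity: dict[str, list[CompositeAnnotation]] = {}
        self._by_term: dict[str, set[str]] = {}
        for m in models:
            self.add_model(m)
        for e in entities:
            self.add_entity(e)
        for a in annotations:
            self.add_annotation(a)

    def add_model(self, model: ModelDescriptor) -> None:
        self.models[model.file] = model

    def add_entity(self, entity: ModelEntity) -> None:
        """Register an entity (possibly unannotated)."""
        if entity.model_file not in self.models:
            stem = entity.model_file.rsplit("/", 1)[-1]
            self.add_model(ModelDescriptor(file=entity.model_file, name=stem))
        self.entities.setdefault(entity.uri, entity)

    def add_annotation(self, annotation: CompositeAnnotation) -> None:
        self.add_entity(annotation.target)
        if annotation in self._by_entity.get(annotation.target.uri, ()):
            return  # set semantics
        self.annotations.append(annotation)
        self._by_entity.setdefault(annotation.target.uri, []).append(annotation)
        for term in annotation.all_terms:
            self._by_term.setdefault(term.uri, set()).add(annotation.target.uri)

    def annotations_for(self, entity_uri: str) -> list[CompositeAnnotation]:
        return list(self._by_entity.get(entity_uri, []))

    def entities_for_term(self, term_uri: str) -> set[str]:
        return set(self._by_term.get(term_uri, set()))

    def model_of(self, entity_uri: str) -> ModelDescriptor:
        entity = self.entities[entity_uri]
        return self.models[entity.model_file]

    @property
    def annotation_set(self) -> frozenset[CompositeAnnotation]:
        return frozenset(self.annotations)

    def rebuild_indexes(self) -> "AnnotatedCorpus":
        """Fresh corpus from the model/entity/annotation sets (idempotence check)."""
        return AnnotatedCorpus(
            models=self.models.values(),
            annotations=self.annotations,
            entities=self.entities.values(),
        )

    def __len__(self) -> int:
        return len(self.annotations)

    def __eq__(self, other):
        if not isinstance(other, AnnotatedCorpus):
            return NotImplemented
        return (
            self.models == other.models
            and self.annotation_set == other.annotation_set
            and set(self.entities) == set(other.entities)
        )
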