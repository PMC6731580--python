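"""Encode/decode composite annotations as RDF, and assemble corpora.

The annotation vocabulary (which predicate carries the physical property, the
chemical, the participant chains, ...) lives in one mapping that can be
overridden from a YAML file, so a different annotation dialect is a config
change rather than a code change.  Location chains are encoded as participant
blank nodes carrying a reference term and an integer order, which keeps the
chains ordered through any round trip.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .annotation import (
    AnnotatedCorpus,
    CompositeAnnotation,
    ModelDescriptor,
    ModelEntity,
    OntologyTerm,
    PrefixRegistry,
    parse_entity_uri,
)
from .cellml import embedded_rdf, parse_cellml
from .errors import AnnotationInvariantError, MalformedUriError, ParseError
from .rdfio import (
    BNode,
    IRI,
    Literal,
    RDF_NS,
    Triple,
    XSD_NS,
    merge_graphs,
    parse_turtle,
    parse_rdfxml,
    read_rdf_file,
    serialize_rdfxml,
    serialize_turtle,
)

ANNOT_NS = "http://purl.org/modeldiscovery/annot#"
RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"

#: slot name → predicate IRI; replaceable via :func:`load_vocabulary`
DEFAULT_VOCABULARY = {
    "entity_class": ANNOT_NS + "ModelEntity",
    "property": ANNOT_NS + "hasPhysicalProperty",
    "chemical": ANNOT_NS + "hasChemicalEntity",
    "source": ANNOT_NS + "hasSourceParticipant",
    "sink": ANNOT_NS + "hasSinkParticipant",
    "located_in": ANNOT_NS + "isLocatedIn",
    "mediator": ANNOT_NS + "hasMediatorParticipant",
    "reference_term": ANNOT_NS + "hasReferenceTerm",
    "order": ANNOT_NS + "hasOrder",
    "species": ANNOT_NS + "hasSpecies",
    "gene": ANNOT_NS + "hasGene",
    "model_name": ANNOT_NS + "hasName",
    "model_workspace": ANNOT_NS + "inWorkspace",
    "model_organ": ANNOT_NS + "forOrgan",
    "model_class": ANNOT_NS + "Model",
}

DEFAULT_PREFIX_MAP = {
    "ann": ANNOT_NS,
    "rdf": RDF_NS,
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": XSD_NS,
}


def load_vocabulary(path: str | Path) -> dict[str, str]:
    """Load a vocabulary override file (YAML mapping slot → predicate IRI)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    vocab = dict(DEFAULT_VOCABULARY)
    unknown = set(data) - set(vocab)
    if unknown:
        raise ValueError(f"unknown vocabulary slots: {sorted(unknown)}")
    vocab.update(data)
    return vocab


# --------------------------------------------------------------------------
# encoding

def encode_annotations(
    corpus: AnnotatedCorpus, vocab: Optional[dict[str, str]] = None
) -> list[Triple]:
    """Corpus → RDF triples (deterministic blank-node numbering)."""
    vocab = vocab or DEFAULT_VOCABULARY
    triples: list[Triple] = []
    counter = 0
    labels: dict[str, str] = {}

    def note_label(term: OntologyTerm) -> None:
        if term.label:
            labels[term.uri] = term.label

    for mfile in sorted(corpus.models):
        model = corpus.models[mfile]
        subj = IRI(model.file)
        triples.append(Triple(subj, IRI(RDF_NS + "type"), IRI(vocab["model_class"])))
        triples.append(Triple(subj, IRI(vocab["model_name"]), Literal(model.name)))
        if model.workspace:
            triples.append(
                Triple(subj, IRI(vocab["model_workspace"]), Literal(model.workspace))
            )
        if model.organ:
            triples.append(Triple(subj, IRI(vocab["model_organ"]), Literal(model.organ)))

    for uri in sorted(corpus.entities):
        triples.append(
            Triple(IRI(uri), IRI(RDF_NS + "type"), IRI(vocab["entity_class"]))
        )

    for ann in sorted(corpus.annotations, key=lambda a: a.target.uri):
        subj = IRI(ann.target.uri)
        triples.append(Triple(subj, IRI(vocab["property"]), IRI(ann.property.uri)))
        note_label(ann.property)
        if ann.chemical:
            triples.append(Triple(subj, IRI(vocab["chemical"]), IRI(ann.chemical.uri)))
            note_label(ann.chemical)
        for slot, chain in (
            ("source", ann.source_location),
            ("sink", ann.sink_location),
            ("located_in", ann.located_in),
        ):
            for idx, term in enumerate(chain):
                counter += 1
                b = BNode(f"p{counter}")
                triples.append(Triple(subj, IRI(vocab[slot]), b))
                triples.append(Triple(b, IRI(vocab["reference_term"]), IRI(term.uri)))
                triples.append(
                    Triple(
                        b,
                        IRI(vocab["order"]),
                        Literal(str(idx), datatype=XSD_NS + "integer"),
                    )
                )
                note_label(term)
        if ann.mediator:
            triples.append(Triple(subj, IRI(vocab["mediator"]), IRI(ann.mediator.uri)))
            note_label(ann.mediator)
        if ann.species:
            triples.append(Triple(subj, IRI(vocab["species"]), Literal(ann.species)))
        if ann.gene:
            triples.append(Triple(subj, IRI(vocab["gene"]), Literal(ann.gene)))

    for uri in sorted(labels):
        triples.append(Triple(IRI(uri), IRI(RDFS_LABEL), Literal(labels[uri])))
    return triples


def write_annotation_graph(
    corpus: AnnotatedCorpus,
    dialect: str = "turtle",
    vocab: Optional[dict[str, str]] = None,
    prefixes: Optional[dict[str, str]] = None,
) -> str:
    """Serialize a corpus's annotation graph to Turtle or RDF/XML text."""
    if dialect not in ("turtle", "rdfxml"):
        raise ValueError(f"dialect must be 'turtle' or 'rdfxml', got {dialect!r}")
    triples = encode_annotations(corpus, vocab)
    pmap = dict(DEFAULT_PREFIX_MAP)
    pmap.update(prefixes or {})
    if dialect == "turtle":
        return serialize_turtle(triples, pmap)
    return serialize_rdfxml(triples, pmap)


# --------------------------------------------------------------------------
# decoding

def read_annotation_graph(
    paths: Sequence[str | Path], dialect: Optional[str] = None
) -> set[Triple]:
    """Union of triples across documents, blank nodes renamed apart.

    ``dialect`` forces a syntax (``turtle``/``rdfxml``); by default each file
    dispatches on its extension.
    """
    graphs = []
    for p in paths:
        p = Path(p)
        if dialect == "turtle":
            graphs.append(parse_turtle(p.read_text(), source=str(p)))
        elif dialect == "rdfxml":
            graphs.append(parse_rdfxml(p.read_text(), source=str(p)))
        else:
            graphs.append(read_rdf_file(p))
    return merge_graphs(graphs)


def _term(
    uri: str, registry: PrefixRegistry, labels: dict[str, str]
) -> OntologyTerm:
    return OntologyTerm.from_uri(uri, registry, label=labels.get(uri))


def extract_annotations(
    models: Iterable[object],
    triples: Iterable[Triple],
    vocab: Optional[dict[str, str]] = None,
    registry: Optional[PrefixRegistry] = None,
    strict: bool = False,
) -> AnnotatedCorpus:
    """Decode every annotation subgraph rooted at a model-entity URI.

    ``models`` may contain :class:`~.cellml.CellmlModel` or
    :class:`~.annotation.ModelDescriptor` objects.  Subgraphs that violate the
    composite-annotation invariants are recorded as warnings (one per entity)
    and skipped unless ``strict``.
    """
    vocab = vocab or DEFAULT_VOCABULARY
    registry = registry or PrefixRegistry()
    triples = list(triples)

    labels: dict[str, str] = {}
    spo: dict[object, dict[str, list]] = {}
    model_meta: dict[str, dict[str, str]] = {}
    for t in triples:
        if t.predicate.value == RDFS_LABEL and isinstance(t.subject, IRI):
            if isinstance(t.object, Literal):
                labels.setdefault(t.subject.value, t.object.lexical)
            continue
        spo.setdefault(t.subject, {}).setdefault(t.predicate.value, []).append(t.object)

    corpus = AnnotatedCorpus()
    for m in models:
        if isinstance(m, ModelDescriptor):
            corpus.add_model(m)
        else:  # CellmlModel
            corpus.add_model(ModelDescriptor(file=m.file, name=m.name))

    # model-level metadata carried in the graph itself
    for subj, props in spo.items():
        if not isinstance(subj, IRI):
            continue
        if any(
            isinstance(o, IRI) and o.value == vocab["model_class"]
            for o in props.get(RDF_NS + "type", [])
        ):
            name = next(
                (o.lexical for o in props.get(vocab["model_name"], [])
                 if isinstance(o, Literal)),
                subj.value,
            )
            ws = next(
                (o.lexical for o in props.get(vocab["model_workspace"], [])
                 if isinstance(o, Literal)),
                None,
            )
            organ = next(
                (o.lexical for o in props.get(vocab["model_organ"], [])
                 if isinstance(o, Literal)),
                None,
            )
            if subj.value not in corpus.models:
                corpus.add_model(
                    ModelDescriptor(file=subj.value, name=name, workspace=ws, organ=organ)
                )
            else:
                old = corpus.models[subj.value]
                corpus.add_model(
                    ModelDescriptor(
                        file=old.file,
                        name=name if name != subj.value else old.name,
                        workspace=ws or old.workspace,
                        organ=organ or old.organ,
                    )
                )

    def decode_chain(objs: list) -> tuple[OntologyTerm, ...]:
        # duplicate (order, term) participants collapse: merged documents may
        # restate the same chain with blank nodes renamed apart
        items: set[tuple[int, str]] = set()
        for o in objs:
            if not isinstance(o, BNode):
                # bare term used as participant: treat as a one-term chain entry
                if isinstance(o, IRI):
                    items.add((len(items), o.value))
                continue
            props = spo.get(o, {})
            terms = [
                x.value for x in props.get(vocab["reference_term"], [])
                if isinstance(x, IRI)
            ]
            orders = [
                int(x.lexical) for x in props.get(vocab["order"], [])
                if isinstance(x, Literal)
            ]
            if terms:
                items.add((orders[0] if orders else len(items), terms[0]))
        return tuple(
            _term(u, registry, labels) for _, u in sorted(items)
        )

    annotation_predicates = {
        vocab[k] for k in ("property", "chemical", "source", "sink",
                           "located_in", "mediator", "species", "gene")
    }

    for subj in sorted(
        (s for s in spo if isinstance(s, IRI)), key=lambda s: s.value
    ):
        props = spo[subj]
        is_entity = any(
            isinstance(o, IRI) and o.value == vocab["entity_class"]
            for o in props.get(RDF_NS + "type", [])
        )
        has_annotation = bool(annotation_predicates & set(props))
        if not (is_entity or has_annotation):
            continue
        try:
            entity = parse_entity_uri(subj.value)
        except MalformedUriError:
            continue  # not an entity-addressed subject
        corpus.add_entity(entity)
        if not has_annotation:
            continue
        try:
            prop_uris = [
                o.value for o in props.get(vocab["property"], []) if isinstance(o, IRI)
            ]
            if not prop_uris:
                raise AnnotationInvariantError(
                    f"{subj.value}: annotation lacks the mandatory physical property"
                )
            chem_uris = [
                o.value for o in props.get(vocab["chemical"], []) if isinstance(o, IRI)
            ]
            med_uris = [
                o.value for o in props.get(vocab["mediator"], []) if isinstance(o, IRI)
            ]
            species = next(
                (o.lexical for o in props.get(vocab["species"], [])
                 if isinstance(o, Literal)), None,
            )
            gene = next(
                (o.lexical for o in props.get(vocab["gene"], [])
                 if isinstance(o, Literal)), None,
            )
            ann = CompositeAnnotation(
                target=entity,
                property=_term(sorted(prop_uris)[0], registry, labels),
                chemical=_term(sorted(chem_uris)[0], registry, labels)
                if chem_uris else None,
                source_location=decode_chain(props.get(vocab["source"], [])),
                sink_location=decode_chain(props.get(vocab["sink"], [])),
                located_in=decode_chain(props.get(vocab["located_in"], [])),
                mediator=_term(sorted(med_uris)[0], registry, labels)
                if med_uris else None,
                species=species,
                gene=gene,
            )
        except AnnotationInvariantError as exc:
            if strict:
                raise
            warnings.warn(str(exc), stacklevel=2)
            continue
        corpus.add_annotation(ann)
    return corpus


# --------------------------------------------------------------------------
# workspace assembly

def load_corpus(
    directory: str | Path,
    vocab: Optional[dict[str, str]] = None,
    registry: Optional[PrefixRegistry] = None,
) -> tuple[AnnotatedCorpus, list]:
    """Assemble a corpus from a workspace-style directory.

    Scans ``*.cellml`` for models (including any embedded RDF blocks) and
    sibling ``*.ttl``/``*.rdf`` documents for annotations.  When the same
    entity is annotated both in-file and in a sibling document, the sibling
    document wins.  Returns ``(corpus, models)``.
    """
    directory = Path(directory)
    vocab = vocab or DEFAULT_VOCABULARY
    cellml_files = sorted(directory.rglob("*.cellml"))
    rdf_files = sorted(
        p for p in list(directory.rglob("*.ttl")) + list(directory.rglob("*.rdf"))
    )
    models = [parse_cellml(p) for p in cellml_files]

    in_file = merge_graphs([embedded_rdf(p) for p in cellml_files])
    sibling = read_annotation_graph(rdf_files)

    sib_corpus = extract_annotations(models, sibling, vocab, registry)
    inf_corpus = extract_annotations(models, in_file, vocab, registry)

    corpus = AnnotatedCorpus(models=sib_corpus.models.values())
    for m in inf_corpus.models.values():
        if m.file not in corpus.models:
            corpus.add_model(m)
    for model in models:
        desc = corpus.models.get(model.file)
        if desc is None or desc.name == desc.file:
            old = corpus.models.get(model.file)
            corpus.add_model(
                ModelDescriptor(
                    file=model.file,
                    name=model.name,
                    workspace=old.workspace if old else None,
                    organ=old.organ if old else None,
                )
            )
    annotated_in_sibling = {a.target.uri for a in sib_corpus.annotations}
    for ann in sib_corpus.annotations:
        corpus.add_annotation(ann)
    for ann in inf_corpus.annotations:
        if ann.target.uri not in annotated_in_sibling:
            corpus.add_annotation(ann)
    for uri, entity in {**inf_corpus.entities, **sib_corpus.entities}.items():
        corpus.add_entity(entity)
    # register every declared variable/component as an (unannotated) entity
    for model in models:
        for comp in model.components:
            corpus.add_entity(ModelEntity(model.file, comp.name))
        for var in model.variables:
            corpus.add_entity(ModelEntity(model.file, var.component, var.name))
    return corpus, models
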