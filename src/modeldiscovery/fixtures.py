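"""Deterministic synthetic corpus of annotated epithelial-transport models.

The generator emulates the shape of a curated model-repository workspace: a
cohort of CellML models of membrane transporters, each with an apical and a
basolateral membrane component plus a cytosol component, flux variables
annotated as composite process annotations (chemical + property + source/sink
anatomy + protein mediator) and concentration variables annotated as state
annotations.  Mediator proteins are emitted as FASTA, mutated from a common
reference at rates that plant known pairwise percent identities, so the
recommender's sequence ranking can be checked against ground truth.

All ontology terms live in a reserved ``https://example.org/fixture/``
namespace: fixture identifiers can never be mistaken for real OPB/FMA/ChEBI/
PR ids.  Output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .annotation import (
    AnnotatedCorpus,
    CompositeAnnotation,
    ModelDescriptor,
    ModelEntity,
    OntologyTerm,
    render_description,
)
from .codec import write_annotation_graph
from .seqsim import ProteinRecord, write_fasta
from .terms import save_label_cache

EX = "https://example.org/fixture/"
AA = "ACDEFGHIKLMNPQRSTVWY"

OPB_FLUX = OntologyTerm(EX + "opb#flux", "OPB", "flux")
OPB_CONC = OntologyTerm(EX + "opb#concentration", "OPB", "concentration")

CHEMICALS = {
    "sodium": OntologyTerm(EX + "chebi#sodium", "CHEBI", "sodium"),
    "hydrogen": OntologyTerm(EX + "chebi#hydrogen", "CHEBI", "hydrogen"),
    "glucose": OntologyTerm(EX + "chebi#glucose", "CHEBI", "glucose"),
}

FMA_LUMEN = OntologyTerm(EX + "fma#lumen_of_proximal_tubule", "FMA", "proximal tubule")
FMA_CYTOSOL = OntologyTerm(EX + "fma#epithelial_cytosol", "FMA", "epithelial cell cytosol")
FMA_INTERSTITIUM = OntologyTerm(EX + "fma#interstitium", "FMA", "interstitial fluid")
FMA_APICAL = OntologyTerm(EX + "fma#apical_plasma_membrane", "FMA", "apical plasma membrane")
FMA_BASOLATERAL = OntologyTerm(
    EX + "fma#basolateral_plasma_membrane", "FMA", "basolateral plasma membrane"
)

#: fixture prefix registry records (stem → prefix)
PREFIX_RECORDS = [
    ("OPB", EX + "opb#"),
    ("CHEBI", EX + "chebi#"),
    ("FMA", EX + "fma#"),
    ("PR", EX + "pr#"),
]

SPECIES_CYCLE = ("Homo sapiens", "Rattus norvegicus", "Mus musculus")

REFERENCE_ACCESSION = "FIXREF"
REFERENCE_LABEL = "sodium/hydrogen exchanger 3"
REFERENCE_GENE = "SLC9A3"


def protein_term(accession: str, label: str) -> OntologyTerm:
    return OntologyTerm(EX + "pr#" + accession, "PR", label)


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of the stated synthetic world.

    Defaults are the ``epithelial-mini`` profile: four models spanning both
    membranes, three chemical species, and candidate mediator proteins
    planted at 90/50/20 percent identity to the reference exchanger.
    """

    n_models: int = 4
    membranes: tuple[str, ...] = ("apical", "basolateral")
    transporters_per_model: int = 2
    chemicals: tuple[str, ...] = ("sodium", "hydrogen", "glucose")
    planted_identities: tuple[float, ...] = (90.0, 50.0, 20.0)
    seed: int = 42
    sequence_length: int = 600

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("need at least one model")
        if any(not (0 <= p <= 100) for p in self.planted_identities):
            raise ValueError("planted identities must lie in [0, 100]")
        unknown = set(self.chemicals) - set(CHEMICALS)
        if unknown:
            raise ValueError(f"unknown fixture chemicals: {sorted(unknown)}")


@dataclass(frozen=True)
class ManifestRow:
    entity_uri: str
    kind: str  # flux | concentration
    chemical: str
    membrane: str  # apical | basolateral | '' for state annotations
    accession: str
    species: str
    gene: str
    description: str


@dataclass
class GeneratedCorpus:
    out_dir: Path
    manifest: list[ManifestRow]
    corpus: AnnotatedCorpus = field(repr=False, default=None)
    records: dict[str, ProteinRecord] = field(default_factory=dict, repr=False)
    planted_accessions: list[str] = field(default_factory=list)

    @property
    def sodium_flux_uris(self) -> list[str]:
        return [r.entity_uri for r in self.manifest
                if r.kind == "flux" and r.chemical == "sodium"]

    @property
    def concentration_uris(self) -> list[str]:
        return [r.entity_uri for r in self.manifest if r.kind == "concentration"]


def _mutate(reference: str, identity: float, rng: random.Random) -> str:
    """Substitute exactly round((1 − identity/100)·L) distinct sites, each to a
    different residue, so the planted identity verifies by direct count."""
    n_mut = round((1.0 - identity / 100.0) * len(reference))
    positions = rng.sample(range(len(reference)), n_mut)
    seq = list(reference)
    for pos in positions:
        choices = [a for a in AA if a != seq[pos]]
        seq[pos] = rng.choice(choices)
    return "".join(seq)


def _cellml_text(name: str, components: dict[str, list[tuple[str, str]]]) -> str:
    """Minimal CellML 1.1 document; every element carries a cmeta:id equal to
    its entity-URI fragment."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<model name="{name}" cmeta:id="{name}"',
        '    xmlns="http://www.cellml.org/cellml/1.1#"',
        '    xmlns:cmeta="http://www.cellml.org/metadata/1.0#">',
    ]
    for comp, variables in components.items():
        lines.append(f'  <component name="{comp}" cmeta:id="{comp}">')
        for vname, units in variables:
            lines.append(
                f'    <variable name="{vname}" units="{units}"'
                f' cmeta:id="{comp}.{vname}" initial_value="0"/>'
            )
        lines.append("  </component>")
    lines.append("</model>")
    return "\n".join(lines) + "\n"


def build_corpus(spec: CorpusSpec) -> GeneratedCorpus:
    """Construct the synthetic corpus in memory (no files written)."""
    master = random.Random(spec.seed)
    reference = "".join(master.choice(AA) for _ in range(spec.sequence_length))

    records: dict[str, ProteinRecord] = {
        REFERENCE_ACCESSION: ProteinRecord(REFERENCE_ACCESSION, reference)
    }
    planted: list[str] = []
    for identity in spec.planted_identities:
        acc = f"FIX{int(round(identity)):03d}"
        rng = random.Random(f"{spec.seed}:{acc}")
        records[acc] = ProteinRecord(acc, _mutate(reference, identity, rng))
        planted.append(acc)

    corpus = AnnotatedCorpus()
    manifest: list[ManifestRow] = []

    for m in range(spec.n_models):
        mfile = f"model_{m:02d}.cellml"
        mname = f"epithelial_transport_{m:02d}"
        species = SPECIES_CYCLE[m % len(SPECIES_CYCLE)]
        corpus.add_model(
            ModelDescriptor(
                file=mfile, name=mname, workspace="fixture-workspace",
                organ="kidney" if m % 2 == 0 else "lung",
            )
        )
        chems_used: set[str] = set()

        for t in range(spec.transporters_per_model):
            if t == 0:
                membrane, chem_name = "apical", "sodium"
                if m == 0:
                    acc, plabel, gene = (
                        REFERENCE_ACCESSION, REFERENCE_LABEL, REFERENCE_GENE,
                    )
                elif m - 1 < len(planted):
                    acc = planted[m - 1]
                    plabel = f"planted transporter {acc}"
                    gene = f"FIXG{m:02d}"
                else:
                    acc, plabel, gene = None, None, None
            else:
                membrane = spec.membranes[t % len(spec.membranes)]
                chem_name = spec.chemicals[(m + t) % len(spec.chemicals)]
                acc, plabel, gene = f"FIXM{m:02d}T{t}", f"generic carrier {m}-{t}", f"FIXG{m:02d}"
            if membrane not in spec.membranes:
                membrane = spec.membranes[0]
            chems_used.add(chem_name)
            if acc is not None and acc not in records:
                rng = random.Random(f"{spec.seed}:{acc}")
                identity = 30.0 + 40.0 * rng.random()  # unrelated carriers
                records[acc] = ProteinRecord(acc, _mutate(reference, identity, rng))

            chem = CHEMICALS[chem_name]
            if membrane == "apical":
                source, sink = (FMA_LUMEN,), (FMA_CYTOSOL,)
            else:
                source, sink = (FMA_CYTOSOL,), (FMA_INTERSTITIUM,)
            var = f"J_{chem_name}_{t}"
            entity = ModelEntity(mfile, membrane, var)
            ann = CompositeAnnotation(
                target=entity,
                property=OPB_FLUX,
                chemical=chem,
                source_location=source,
                sink_location=sink,
                mediator=protein_term(acc, plabel) if acc else None,
                species=species if acc else None,
                gene=gene,
            )
            corpus.add_annotation(ann)
            manifest.append(
                ManifestRow(
                    entity_uri=entity.uri, kind="flux", chemical=chem_name,
                    membrane=membrane, accession=acc or "", species=species if acc else "",
                    gene=gene or "", description=render_description(ann),
                )
            )

        for chem_name in sorted(chems_used):
            chem = CHEMICALS[chem_name]
            entity = ModelEntity(mfile, "cytosol", f"C_{chem_name}")
            ann = CompositeAnnotation(
                target=entity,
                property=OPB_CONC,
                chemical=chem,
                located_in=(FMA_CYTOSOL,),
            )
            corpus.add_annotation(ann)
            manifest.append(
                ManifestRow(
                    entity_uri=entity.uri, kind="concentration", chemical=chem_name,
                    membrane="", accession="", species="", gene="",
                    description=render_description(ann),
                )
            )

    return GeneratedCorpus(
        out_dir=Path("."), manifest=manifest, corpus=corpus,
        records=records, planted_accessions=planted,
    )


def fixture_labels(generated: GeneratedCorpus) -> dict[str, str]:
    labels: dict[str, str] = {}
    for ann in generated.corpus.annotations:
        for term in ann.all_terms:
            if term.label:
                labels[term.uri] = term.label
    return labels


def fixture_dictionary_records(
    generated: Optional[GeneratedCorpus] = None,
) -> list[tuple[str, str, str, str]]:
    """(key, curie, uri, label) records for the fixture vocabulary.

    Covers the epithelial-transport vocabulary: flux, concentration, the
    chemical species, membrane sides and compartments; with a generated
    corpus, also the mediator protein names.
    """
    base = [
        ("flux", OPB_FLUX),
        ("concentration", OPB_CONC),
        *[(name, term) for name, term in sorted(CHEMICALS.items())],
        ("proximal tubule", FMA_LUMEN),
        ("cytosol", FMA_CYTOSOL),
        ("interstitium", FMA_INTERSTITIUM),
        ("apical", FMA_APICAL),
        ("basolateral", FMA_BASOLATERAL),
        ("membrane", FMA_APICAL),
        ("membrane", FMA_BASOLATERAL),
    ]
    records = []
    for key, term in base:
        local = term.uri.rsplit("#", 1)[-1]
        records.append((key, f"{term.prefix}:{local}", term.uri, term.label or ""))
    if generated is not None:
        seen = set()
        for ann in generated.corpus.annotations:
            med = ann.mediator
            if med and med.uri not in seen:
                seen.add(med.uri)
                local = med.uri.rsplit("#", 1)[-1]
                records.append(
                    (med.label.lower(), f"PR:{local}", med.uri, med.label or "")
                )
    return records


def write_dictionary(records: Sequence[tuple[str, str, str, str]], path: Path) -> None:
    lines = ["# key\tcurie\turi\tlabel"]
    for rec in sorted(records):
        lines.append("\t".join(rec))
    path.write_text("\n".join(lines) + "\n")


def generate_corpus(spec: CorpusSpec, out_dir: str | Path) -> GeneratedCorpus:
    """Write the synthetic workspace to ``out_dir`` and return its manifest.

    Emits per model one CellML file and one Turtle annotation document, plus
    ``proteins.fasta``, ``dictionary.tsv``, ``labels.tsv``, ``prefixes.tsv``
    and ``manifest.tsv``.  Byte-identical for identical specs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    generated = build_corpus(spec)
    generated.out_dir = out
    corpus = generated.corpus

    by_model: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for uri in sorted(corpus.entities):
        e = corpus.entities[uri]
        units = "flux_units" if e.variable and e.variable.startswith("J_") else "molar"
        if e.variable:
            by_model.setdefault(e.model_file, {}).setdefault(e.component, []).append(
                (e.variable, units)
            )
    for mfile in sorted(corpus.models):
        model = corpus.models[mfile]
        comps = {
            c: sorted(vs) for c, vs in sorted(by_model.get(mfile, {}).items())
        }
        (out / mfile).write_text(_cellml_text(model.name, comps))

        per_model = AnnotatedCorpus(models=[model])
        for ann in corpus.annotations:
            if ann.target.model_file == mfile:
                per_model.add_annotation(ann)
        ttl = write_annotation_graph(per_model, dialect="turtle")
        (out / (Path(mfile).stem + ".ttl")).write_text(ttl)

    write_fasta(generated.records.values(), out / "proteins.fasta")
    save_label_cache(fixture_labels(generated), out / "labels.tsv")
    write_dictionary(fixture_dictionary_records(generated), out / "dictionary.tsv")
    (out / "prefixes.tsv").write_text(
        "\n".join(f"{p}\t{stem}" for p, stem in PREFIX_RECORDS) + "\n"
    )
    rows = ["\t".join(
        ("entity_uri", "kind", "chemical", "membrane", "accession",
         "species", "gene", "description")
    )]
    for r in generated.manifest:
        rows.append("\t".join(
            (r.entity_uri, r.kind, r.chemical, r.membrane, r.accession,
             r.species, r.gene, r.description)
        ))
    (out / "manifest.tsv").write_text("\n".join(rows) + "\n")
    return generated
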