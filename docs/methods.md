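# Methods

## Annotation model

A composite annotation binds one model entity — a variable or component of a
CellML 1.0/1.1 document, addressed as `file#component.variable` — to terms
from reference ontologies:

| slot            | ontology   | cardinality | meaning                              |
|-----------------|------------|-------------|--------------------------------------|
| property        | OPB        | 1 (required)| biophysical property (flux, concentration) |
| chemical        | ChEBI      | 0–1         | chemical species                     |
| source/sink     | FMA        | chains      | participants of a process (flux)     |
| located_in      | FMA        | chain       | compartment of a state (concentration) |
| mediator        | PR/UniProt | 0–1         | transport protein                    |
| species, gene   | plain text | 0–1         | experimental context                 |

Invariants: a process annotation has at least one of source/sink and no
located-in chain; chains are ordered most-specific-first and contain no
duplicate terms. Entity URIs split their fragment at the **first** dot
(component identifiers cannot contain dots; variable names may), so
parse∘construct is the identity on all valid entities. Ontology terms are
equal iff their URIs are equal after whitespace trimming — no case folding,
since ontology URIs are case-sensitive. Ontology prefixes (OPB/FMA/CHEBI/PR/
GO/UNIPROT) are classified from a configurable stem registry; unknown stems
classify as OTHER rather than failing, so foreign vocabularies degrade
gracefully.

Species and gene are plain strings, not ontology terms: discovery interfaces
display them as text columns and nothing joins on them.

## RDF encoding

Annotations serialize through a vocabulary of predicate IRIs (one YAML-
overridable mapping, `data/vocabulary.yaml`), with location chains encoded as
participant blank nodes carrying a reference term and an integer order. This
keeps chains ordered through any round trip while remaining plain RDF.
Serialization is deterministic — subjects sorted, blank nodes renumbered by a
neighborhood signature — so a corpus written twice is byte-identical, and
documents double-serialize stably. Decoding collapses participant duplicates
with identical (order, term), which makes merging a previously written index
with its source documents idempotent. Annotations may live inside the CellML
file's `rdf:RDF` block or in sibling Turtle/RDF-XML documents; both are
scanned and sibling documents win on conflict, covering both deposit styles.
CellML 2.0 is rejected explicitly (different metadata mechanism) rather than
silently mis-parsed.

The Turtle and RDF/XML codecs are implemented in-package on the standard
library. They cover the constructs the annotation profile uses (IRIs, blank
nodes, plain/typed/language literals, prefixed names, `;`/`,` continuations,
nested node elements) — not the full W3C grammars; unsupported constructs
fail loudly with file and line.

## Querying

The triple store evaluates conjunctive basic-graph-pattern queries with an
ordered nested-loop join, most selective pattern first (fewest unbound
wildcards, then fewest index candidates). Corpora are small — tens of models,
a few thousand triples — so correctness and deterministic ordering (rows
sorted by bound values) outrank speed. Literals compare by lexical form and
datatype; there is no numeric value-space coercion. The full SPARQL grammar
is deliberately not parsed; a thin adapter renders pattern lists as SPARQL
1.1 `SELECT DISTINCT` text for remote read-only endpoints and parses the JSON
results format, and a loopback integration test asserts local/remote solution
sets are identical.

Search proceeds in cascading stages: (1) mapped terms match annotation slots
and query tokens match model names (case-insensitive substring); (2)
surviving entities are enriched with protein accessions via their mediator
participant; (3) species and gene literals are fetched. Stages enrich, never
filter: entities without proteins still appear. Both variable-level and
component-level entities count as results; variable-level entities win ties.
Unannotated entities are excluded from results — with no annotation there is
no biological meaning to rank or display.

### Ranking weights

`score = Σ w_s·[slot s matched]` with defaults
property 0.35, chemical 0.35, location 0.15, mediator 0.10, model-name 0.05
(validated positive, summing to 1; config-exposed). The defaults are an
artifact choice constrained qualitatively: property+chemical must beat any
single slot so that "flux of sodium" puts sodium fluxes above everything
merely sodium- or flux-related. Term mapping is exact-match on a static
dictionary (`key<TAB>prefix:id<TAB>uri[<TAB>label]`), multi-word keys greedily
longest-first; fuzzy matching and synonym expansion are out of scope. Label
resolution is cache-first from a flat `uri<TAB>label` file; an OLS-style
remote lookup can fill misses but ships disabled.

## Sequence similarity

Global alignment is Needleman–Wunsch with linear gaps and deterministic
traceback (diagonal > up > left on ties). Default scoring is match +1,
mismatch 0, gap −1: the requirement is a stable *ranking* signal among
related transporters, not biology-grade alignment; a substitution table can
be supplied for realistic proteins. Percent identity counts identical columns
over columns where both sequences carry residues (gap-excluded, the Clustal
convention), rounded half-up to two decimals; an alignment with no
co-residue columns is an error rather than 0/0. The local pairwise matrix is
the default; remote mode can instead submit sequences to a Clustal-style
service and parse its percent-identity matrix text, which may differ from
pairwise values since MSA-derived identities are computed on the multiple
alignment — the difference is documented, not hidden.

## Recommendation

Candidates are annotated entities of other models sharing ≥1 anatomical term
with the selection (union over all chains). Candidates with protein sequences
are ranked by descending identity to the selected protein and always precede
location-only candidates, which rank by shared-term count;
`rank_score = identity/100` or `0.5 × shared/|selected terms|` respectively.
Sequence-fetch failures degrade that candidate to location-only with a
warning, never abort. With the flux chains used here (lumen→cytosol across
the apical membrane, cytosol→interstitium across the basolateral), the
cytosol term is shared across membranes, so apical and basolateral
populations separate by shared-term *count* (2 within a membrane vs 1
across) and by the sequence group, not by empty intersection. How semantic
and sequence evidence combine into one ranking is an open design point; the
grouped ordering here (sequence evidence first) is the package's documented
choice.

## Synthetic corpus

The generator emulates a curated workspace of annotated epithelial-transport
models: per model an apical, basolateral and cytosol component; apical fluxes
lumen→cytosol, basolateral fluxes cytosol→interstitium; cytosolic
concentration variables per chemical; mediator proteins with accessions,
species and gene strings. Defaults (the `epithelial-mini` profile): 4 models,
both membranes, 2 transporters/model, chemicals sodium/hydrogen/glucose,
planted identities 90/50/20 %, sequence length 600, seed 42. Planted
identities are realized by substituting exactly `round((1−id/100)·L)`
distinct sites (each to a different residue) under a per-accession RNG
stream — a deterministic realization of a per-site substitution rate that
makes the identity verifiable by direct count. Model 0's apical sodium flux
reproduces the canonical description ("sodium flux from proximal tubule to
epithelial cell cytosol via sodium/hydrogen exchanger 3") so rendering is
pinned to a known string. All fixture terms live in the reserved
`https://example.org/fixture/` namespace and can never be mistaken for real
ontology identifiers.

What the generator does *not* emulate: real model mathematics (components
carry variables but no MathML), CellML imports, hierarchical workspaces,
curation noise (misspelled labels, partial annotations), or realistic protein
families — mutations are uniform i.i.d. substitutions, so identity ≈ planted
value but alignment of heavily mutated pairs may recover slightly more
identity via gaps (20 % plants measure ≈20.5 %). A green suite therefore
establishes the machinery — round trips, join correctness, ranking
properties, planted-identity recovery — on this stated world, not performance
on the curated public cohort; the latter is exercised only by the optional
network script (`scripts/tier2_external.py`).

## Numerical and degenerate-input choices

- Percent identities use decimal half-up rounding to 2 places (banker's
  rounding would bias .005 cases down).
- Alignment DP uses float scores; the exhaustive-enumeration oracle in the
  tests pins optimality for short sequences, and Biopython's independent
  aligner cross-checks scores on longer ones.
- Empty query, fully unmapped query, empty store, empty corpus and
  single-model recommendation all return empty results rather than erroring;
  malformed URIs, empty sequences and duplicate accessions raise typed
  errors.
- Determinism everywhere: fixed seed ⇒ byte-identical fixture trees; search
  and recommendation order is a pure sort key, so results are stable across
  runs and under corpus extension/removal of unrelated entries.

## Known limitations

- The RDF codecs parse the annotation profile plus common constructs, not
  full Turtle/RDF-XML (no collections, `parseType="Collection"`, or quoted
  triples).
- BGP queries only — no OPTIONAL/UNION/FILTER; remote stores are read-only.
- Exact-match dictionary lookup; no lemmatization or spelling correction.
- Linear gap penalties only; no affine gaps or alignment profiles.
- Recommendation evidence is limited to shared anatomy and sequence
  similarity; no collaborative filtering or usage signals.
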