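# modeldiscovery

Composite semantic annotation and discovery of CellML biosimulation models.

Repositories of physiological models are only useful to the extent that their
contents can be *found*. A CellML model of an epithelial sodium transporter is,
to a text index, a bag of variable names like `J_NHE3_Na` — meaningless to a
researcher searching for "flux of sodium". This package addresses that gap for
computational physiologists and model curators: it attaches machine-readable
**composite annotations** to model variables, indexes them as RDF, and answers
free-text discovery queries with ranked, biologically described model entities
plus recommendations of similar models.

## The method

**Composite annotation.** Each model variable (addressed as
`file#component.variable`, anchored to the CellML metadata identifier) is
described by combining terms from reference ontologies: a biophysical property
*P* (OPB: flux, concentration, ...), a chemical species *C* (ChEBI), ordered
chains of anatomical locations *L* (FMA), and optionally a protein mediator *M*
(PR/UniProt) with species and gene metadata. A process annotation (a flux)
carries source and sink location chains; a state annotation (a concentration)
carries a located-in chain. The annotation renders deterministically to text,
e.g.

> sodium flux from proximal tubule to epithelial cell cytosol via
> sodium/hydrogen exchanger 3

**Discovery.** A query *q* is tokenized and mapped to ontology terms through a
static exact-match dictionary (`flux → OPB`, `sodium → ChEBI`). Cascading
basic-graph-pattern queries over the corpus triple store first match annotation
slots and model names, then enrich hits with protein accessions and
species/gene. Each entity scores

```
score(e) = Σ_s  w_s · 1[some mapped term matches slot s of e],
s ∈ {property, chemical, location, mediator, model_name},
w = (0.35, 0.35, 0.15, 0.10, 0.05)
```

so an entity matching *both* "flux" and "sodium" (0.70) always outranks a
merely sodium-related one (0.35), while the latter still appears lower down.

**Recommendation.** For a selected entity, candidate entities of other models
sharing an anatomical term are ranked: candidates whose mediator proteins have
sequences are ordered by descending percent identity to the selected protein
(Needleman–Wunsch global alignment; identity counted over columns where both
sequences have residues, rounded half-up to 2 decimals), followed by
location-only candidates ordered by shared-term count. Same-protein /
other-species and same-workspace organ models are flagged as alternative
groups.

## Worked example

Generate the bundled synthetic workspace (four annotated epithelial-transport
models, mediator proteins planted at 90/50/20 % identity to a reference
exchanger), then query and explore it:

```console
$ modeldisco fixtures generate --seed 42 --out demo_ws
$ modeldisco query "flux of sodium" --corpus demo_ws --top 4
0.7000  model_00.cellml#apical.J_sodium_0
        sodium flux from proximal tubule to epithelial cell cytosol via sodium/hydrogen exchanger 3
0.7000  model_01.cellml#apical.J_sodium_0
        sodium flux from proximal tubule to epithelial cell cytosol via planted transporter FIX090
0.7000  model_02.cellml#apical.J_sodium_0
        sodium flux from proximal tubule to epithelial cell cytosol via planted transporter FIX050
0.7000  model_02.cellml#basolateral.J_sodium_1
        sodium flux from epithelial cell cytosol to interstitial fluid via generic carrier 2-1
```

Every sodium-flux variable scores 0.70 (property + chemical matched);
sodium concentrations and non-sodium fluxes follow at 0.35. Selecting the top
entity shows its overview card and similar models:

```console
$ modeldisco describe "model_00.cellml#apical.J_sodium_0" --corpus demo_ws
entity:     model_00.cellml#apical.J_sodium_0
meaning:    sodium flux from proximal tubule to epithelial cell cytosol via sodium/hydrogen exchanger 3
location:   proximal tubule, epithelial cell cytosol
species:    Homo sapiens
gene:       SLC9A3
protein:    sodium/hydrogen exchanger 3
accession:  FIXREF

$ modeldisco recommend "model_00.cellml#apical.J_sodium_0" --corpus demo_ws
0.9000  sim= 90.00  model_01.cellml#apical.J_sodium_0
0.5000  sim= 50.00  model_02.cellml#apical.J_sodium_0
0.3467  sim= 34.67  model_01.cellml#basolateral.J_glucose_1
...
```

The similarity column recovers the planted 90/50/20 % identities (20 %
measures 20.53 because the optimal alignment of heavily mutated sequences may
use a few gaps); recommendations with sequence evidence always precede
location-only ones.

The library surface mirrors the CLI: `generate_corpus`, `load_corpus`,
`search`, `overview`, `recommend`, `similarity_matrix`, plus a `TripleStore`
with `query_bgp` and a `SparqlEndpoint` adapter for remote read-only stores.
See `docs/methods.md` for the model, parameters and limitations.

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch — generates
the synthetic workspace for the given seed, ingests it from disk, verifies the
ingested annotation set against the generator's manifest, executes the
"flux of sodium" discovery query, and computes the recommender's similarity
ranking — then writes the results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/tier2_external.py` (manual, network required) checks the package
against the public exemplar workspace and UniProt sequences.
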