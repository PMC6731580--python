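"""Discovery ranking: scoring arithmetic, cascading search, order properties."""

import random

import pytest

from modeldiscovery.annotation import (
    AnnotatedCorpus,
    CompositeAnnotation,
    ModelDescriptor,
    ModelEntity,
    OntologyTerm,
)
from modeldiscovery.search import (
    CorpusStore,
    DEFAULT_WEIGHTS,
    SLOTS,
    score_entity,
    search,
    validate_weights,
)
from modeldiscovery.terms import map_tokens, tokenize


class TestScoreEntity:
    def test_property_plus_chemical_is_070(self):
        assert score_entity(["property", "chemical"]) == pytest.approx(0.70)

    def test_no_match_scores_zero(self):
        assert score_entity([]) == 0

    def test_random_subsets_equal_recomputed_sum(self):
        rng = random.Random(5)
        for _ in range(200):
            slots = [s for s in SLOTS if rng.random() < 0.5]
            expected = sum(DEFAULT_WEIGHTS[s] for s in set(slots))
            assert score_entity(slots) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "weights",
        [
            {"property": 0.5, "chemical": 0.5},  # missing slots
            {**DEFAULT_WEIGHTS, "property": -0.1},
            {s: 0.3 for s in SLOTS},  # does not sum to 1
        ],
    )
    def test_invalid_weights_rejected(self, weights):
        with pytest.raises(ValueError):
            validate_weights(weights)


class TestSearch:
    def test_sodium_flux_entities_outrank_concentrations(self, ingested):
        generated, corpus, _, dictionary, labels = ingested
        ranked = search(corpus, dictionary, "flux of sodium", labels=labels)
        position = {r.entity.uri: i for i, r in enumerate(ranked.results)}
        flux_uris = generated.sodium_flux_uris
        conc_uris = [u for u in generated.concentration_uris if u in position]
        assert flux_uris and conc_uris
        for f in flux_uris:
            assert f in position
            for c in conc_uris:
                assert position[f] < position[c]

    def test_scores_non_increasing_and_ties_deterministic(self, ingested):
        _, corpus, _, dictionary, labels = ingested
        ranked = search(corpus, dictionary, "flux of sodium", labels=labels)
        scores = [r.score for r in ranked.results]
        assert scores == sorted(scores, reverse=True)
        again = search(corpus, dictionary, "flux of sodium", labels=labels)
        assert [r.entity.uri for r in again.results] == [
            r.entity.uri for r in ranked.results
        ]

    def test_unmapped_query_reports_diagnostic(self, ingested):
        _, corpus, _, dictionary, labels = ingested
        ranked = search(corpus, dictionary, "xyzzy", labels=labels)
        assert ranked.results == [] and ranked.unmapped == ["xyzzy"]

    def test_cascade_enriches_with_protein_species_gene(self, ingested):
        generated, corpus, _, dictionary, labels = ingested
        ranked = search(corpus, dictionary, "flux of sodium", labels=labels)
        manifest = {r.entity_uri: r for r in generated.manifest}
        for result in ranked.results:
            row = manifest[result.entity.uri]
            assert (result.protein or "") == row.accession
            assert (result.species or "") == row.species
            assert (result.gene or "") == row.gene

    def test_descriptions_match_manifest(self, ingested):
        generated, corpus, _, dictionary, labels = ingested
        ranked = search(corpus, dictionary, "flux of sodium", labels=labels)
        manifest = {r.entity_uri: r.description for r in generated.manifest}
        for result in ranked.results:
            assert result.description == manifest[result.entity.uri]

    def test_ordering_equals_brute_force_scorer(self, ingested):
        """Every entity scored independently, then sorted: same order."""
        generated, corpus, _, dictionary, labels = ingested
        query = "flux of sodium"
        mapped = map_tokens(dictionary, tokenize(query))
        mapped_uris = {t.uri for _, t in mapped.hits}
        tokens = tokenize(query)

        expected = []
        for ann in corpus.annotations:
            slots = set()
            if ann.property.uri in mapped_uris:
                slots.add("property")
            if ann.chemical and ann.chemical.uri in mapped_uris:
                slots.add("chemical")
            if any(t.uri in mapped_uris for t in ann.location_terms):
                slots.add("location")
            if ann.mediator and ann.mediator.uri in mapped_uris:
                slots.add("mediator")
            model = corpus.models[ann.target.model_file]
            if any(tok in model.name.lower() for tok in tokens):
                slots.add("model_name")
            score = sum(DEFAULT_WEIGHTS[s] for s in slots)
            if score > 0:
                expected.append(
                    (-score, ann.target.variable is None, model.name, ann.target.uri)
                )
        expected.sort()
        ranked = search(corpus, dictionary, query, labels=labels)
        assert [r.entity.uri for r in ranked.results] == [e[3] for e in expected]


def _toy_corpus():
    prop = OntologyTerm("urn:t:flux", "OPB", "flux")
    chem = OntologyTerm("urn:t:na", "CHEBI", "sodium")
    loc = OntologyTerm("urn:t:cyt", "FMA", "cytosol")
    corpus = AnnotatedCorpus()
    corpus.add_model(ModelDescriptor("a.cellml", "model_a"))
    corpus.add_model(ModelDescriptor("b.cellml", "model_b"))
    both = CompositeAnnotation(
        target=ModelEntity("a.cellml", "X", "j"), property=prop, chemical=chem,
        source_location=(loc,),
    )
    chem_only = CompositeAnnotation(
        target=ModelEntity("b.cellml", "Y", "c"),
        property=OntologyTerm("urn:t:conc", "OPB", "concentration"),
        chemical=chem, located_in=(loc,),
    )
    corpus.add_annotation(both)
    corpus.add_annotation(chem_only)
    return corpus, prop, chem


class TestRankingProperties:
    def test_slot_superset_never_ranks_below_subset(self, ingested):
        generated, corpus, _, dictionary, labels = ingested
        ranked = search(corpus, dictionary, "flux of sodium", labels=labels)
        slot_sets = {
            r.entity.uri: frozenset(s for _, s in r.matched_terms)
            for r in ranked.results
        }
        order = [r.entity.uri for r in ranked.results]
        for i, a in enumerate(order):
            for b in order[:i]:  # b ranked above a
                assert not (slot_sets[b] < slot_sets[a]), (
                    f"{a} matches strictly more slots than {b} but ranks below"
                )

    def test_adding_unrelated_model_preserves_relative_order(self, ingested):
        generated, corpus, _, dictionary, labels = ingested
        before = [
            r.entity.uri
            for r in search(corpus, dictionary, "flux of sodium", labels=labels).results
        ]
        extended = corpus.rebuild_indexes()
        extended.add_model(ModelDescriptor("zzz.cellml", "unrelated_membrane_model"))
        extended.add_annotation(
            CompositeAnnotation(
                target=ModelEntity("zzz.cellml", "Q", "v"),
                property=OntologyTerm("urn:other:prop", "OTHER", "voltage"),
                located_in=(OntologyTerm("urn:other:loc", "OTHER", "axon"),),
            )
        )
        after = [
            r.entity.uri
            for r in search(extended, dictionary, "flux of sodium", labels=labels).results
        ]
        assert [u for u in after if u in set(before)] == before
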