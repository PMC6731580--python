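"""CellML parsing, RDF round trips and annotation extraction."""

import random

import pytest

from modeldiscovery.annotation import (
    AnnotatedCorpus,
    CompositeAnnotation,
    ModelEntity,
    OntologyTerm,
    render_description,
)
from modeldiscovery.cellml import parse_cellml
from modeldiscovery.codec import (
    extract_annotations,
    read_annotation_graph,
    write_annotation_graph,
)
from modeldiscovery.errors import ParseError, UnsupportedDialectError
from modeldiscovery.fixtures import CorpusSpec, build_corpus, generate_corpus
from modeldiscovery.rdfio import (
    BNode,
    IRI,
    Literal,
    Triple,
    canonical_triples,
    merge_graphs,
    parse_rdfxml,
    parse_turtle,
    serialize_rdfxml,
    serialize_turtle,
)

CELLML_HEAD = (
    '<?xml version="1.0"?>\n'
    '<model name="{name}" xmlns="http://www.cellml.org/cellml/1.0#"'
    ' xmlns:cmeta="http://www.cellml.org/metadata/1.0#">'
)


class TestParseCellml:
    def test_empty_component(self, tmp_path):
        p = tmp_path / "mini.cellml"
        p.write_text(CELLML_HEAD.format(name="mini") + '<component name="C"/></model>')
        model = parse_cellml(p)
        assert model.n_components == 1
        assert model.n_variables == 0

    def test_generator_counts_are_exact(self, workspace):
        generated, out = workspace
        spec = CorpusSpec()
        for path in sorted(out.glob("*.cellml")):
            model = parse_cellml(path)
            # each membrane component holds flux variables, cytosol the rest
            per_model = [
                e for e in generated.corpus.entities.values()
                if e.model_file == path.name and e.variable
            ]
            assert model.n_variables == len(per_model)
            assert {c.name for c in model.components} <= {
                "apical", "basolateral", "cytosol"
            }

    def test_metadata_ids_read_back(self, tmp_path):
        p = tmp_path / "m.cellml"
        p.write_text(
            CELLML_HEAD.format(name="m")
            + '<component name="C" cmeta:id="C">'
            '<variable name="v" units="molar" cmeta:id="C.v"/>'
            "</component></model>"
        )
        model = parse_cellml(p)
        assert model.components[0].metadata_id == "C"
        assert model.variables[0].metadata_id == "C.v"

    def test_malformed_xml_reports_position(self, tmp_path):
        p = tmp_path / "broken.cellml"
        p.write_text("<model><component></model>")
        with pytest.raises(ParseError, match=r"line"):
            parse_cellml(p)

    def test_cellml_2_rejected_explicitly(self, tmp_path):
        p = tmp_path / "v2.cellml"
        p.write_text('<model xmlns="http://www.cellml.org/cellml/2.0#" name="m"/>')
        with pytest.raises(UnsupportedDialectError, match="2.0"):
            parse_cellml(p)

    def test_unknown_namespace_named_in_error(self, tmp_path):
        p = tmp_path / "x.cellml"
        p.write_text('<model xmlns="http://sbml.org/sbml/level3#" name="m"/>')
        with pytest.raises(UnsupportedDialectError, match="sbml.org"):
            parse_cellml(p)

    def test_sibling_order_does_not_matter(self, tmp_path):
        body = [
            '<component name="A"><variable name="x" units="molar"/></component>',
            '<component name="B"><variable name="y" units="molar"/></component>',
        ]
        p1, p2 = tmp_path / "a.cellml", tmp_path / "b.cellml"
        p1.write_text(CELLML_HEAD.format(name="m") + "".join(body) + "</model>")
        p2.write_text(CELLML_HEAD.format(name="m") + "".join(body[::-1]) + "</model>")
        m1, m2 = parse_cellml(p1), parse_cellml(p2)
        assert sorted(c.name for c in m1.components) == sorted(
            c.name for c in m2.components
        )
        assert sorted((v.component, v.name) for v in m1.variables) == sorted(
            (v.component, v.name) for v in m2.variables
        )


class TestRdfRoundTrips:
    def test_empty_document(self, tmp_path):
        p = tmp_path / "empty.ttl"
        p.write_text("")
        assert read_annotation_graph([p]) == set()

    def test_turtle_round_trip_is_isomorphic(self, workspace):
        generated, _ = workspace
        triples = canonical_triples(
            parse_turtle(write_annotation_graph(generated.corpus, "turtle"))
        )
        again = canonical_triples(parse_turtle(serialize_turtle(triples)))
        assert triples == again

    def test_rdfxml_round_trip_is_isomorphic(self, workspace):
        generated, _ = workspace
        doc = write_annotation_graph(generated.corpus, "rdfxml")
        triples = canonical_triples(parse_rdfxml(doc))
        again = canonical_triples(parse_rdfxml(serialize_rdfxml(triples)))
        assert triples == again

    def test_double_serialization_is_byte_stable(self, workspace):
        generated, _ = workspace
        doc1 = write_annotation_graph(generated.corpus, "turtle")
        doc2 = serialize_turtle(
            parse_turtle(doc1),
            prefixes=None,
        )
        # reserialize without prefixes still yields identical triples text modulo header
        body1 = [l for l in doc1.splitlines() if l and not l.startswith("@prefix")]
        assert len(body1) > 0
        doc3 = write_annotation_graph(
            extract_annotations([], parse_turtle(doc1)), "turtle"
        )
        # full pipeline determinism: same corpus -> same bytes
        assert write_annotation_graph(generated.corpus, "turtle") == doc1

    def test_shared_bnode_labels_kept_apart_across_documents(self, tmp_path):
        doc = '@prefix ex: <urn:ex#> .\n_:shared ex:p ex:o .\n'
        p1, p2 = tmp_path / "a.ttl", tmp_path / "b.ttl"
        p1.write_text(doc)
        p2.write_text(doc)
        merged = read_annotation_graph([p1, p2])
        subjects = {t.subject for t in merged}
        assert len(merged) == 2 and len(subjects) == 2

    def test_turtle_syntax_error_names_file_and_line(self, tmp_path):
        p = tmp_path / "bad.ttl"
        p.write_text("<urn:s> <urn:p>\n<urn:s2> .\n<oops")
        with pytest.raises(ParseError, match="bad.ttl"):
            read_annotation_graph([p])


NHE3_GRAPH = """
@prefix ann: <http://purl.org/modeldiscovery/annot#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .
@prefix f: <urn:fix:> .

<weinstein_1995.cellml#NHE3.J_NHE3_Na> a ann:ModelEntity ;
    ann:hasPhysicalProperty f:flux ;
    ann:hasChemicalEntity f:sodium ;
    ann:hasSourceParticipant _:s0 ;
    ann:hasSinkParticipant _:k0 ;
    ann:hasMediatorParticipant f:nhe3 .
_:s0 ann:hasReferenceTerm f:pt ; ann:hasOrder "0"^^xsd:integer .
_:k0 ann:hasReferenceTerm f:cyt ; ann:hasOrder "0"^^xsd:integer .
f:flux rdfs:label "flux" .
f:sodium rdfs:label "sodium" .
f:pt rdfs:label "proximal tubule" .
f:cyt rdfs:label "epithelial cell cytosol" .
f:nhe3 rdfs:label "sodium/hydrogen exchanger 3" .
"""


class TestExtractAnnotations:
    def test_nhe3_graph_decodes_to_canonical_description(self):
        corpus = extract_annotations([], parse_turtle(NHE3_GRAPH))
        assert len(corpus) == 1
        ann = corpus.annotations[0]
        assert ann.target.uri == "weinstein_1995.cellml#NHE3.J_NHE3_Na"
        assert render_description(ann) == (
            "sodium flux from proximal tubule to epithelial cell cytosol "
            "via sodium/hydrogen exchanger 3"
        )

    def test_non_entity_triples_yield_empty_corpus(self):
        triples = parse_turtle(
            "<urn:a> <urn:p> <urn:b> .\n<urn:b> <urn:p> \"text\" .\n"
        )
        corpus = extract_annotations([], triples)
        assert len(corpus) == 0

    def test_invariant_violation_warns_not_fatal(self):
        bad = parse_turtle(
            "@prefix ann: <http://purl.org/modeldiscovery/annot#> .\n"
            "<m.cellml#C.v> ann:hasChemicalEntity <urn:na> .\n"  # property missing
        )
        with pytest.warns(UserWarning, match="physical property"):
            corpus = extract_annotations([], bad)
        assert len(corpus) == 0
        assert "m.cellml#C.v" in corpus.entities  # retained as unannotated

    def test_unannotated_entities_are_retained(self):
        triples = parse_turtle(
            "@prefix ann: <http://purl.org/modeldiscovery/annot#> .\n"
            "<m.cellml#C.v> a ann:ModelEntity .\n"
        )
        corpus = extract_annotations([], triples)
        assert list(corpus.entities) == ["m.cellml#C.v"]
        assert len(corpus) == 0

    @pytest.mark.parametrize("dialect", ["turtle", "rdfxml"])
    def test_generated_corpora_round_trip_exactly(self, dialect, tmp_path):
        for seed in (1, 2, 3):
            spec = CorpusSpec(n_models=2, seed=seed, sequence_length=50)
            generated = build_corpus(spec)
            doc = write_annotation_graph(generated.corpus, dialect)
            parser = parse_turtle if dialect == "turtle" else parse_rdfxml
            recovered = extract_annotations([], parser(doc))
            assert recovered.annotation_set == generated.corpus.annotation_set

    def test_sibling_documents_override_in_file_annotations(self, tmp_path):
        (tmp_path / "m.cellml").write_text(
            CELLML_HEAD.format(name="m")
            + '<component name="C" cmeta:id="C">'
            '<variable name="v" units="molar" cmeta:id="C.v"/></component>'
            '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"'
            ' xmlns:ann="http://purl.org/modeldiscovery/annot#">'
            '<rdf:Description rdf:about="#C.v">'
            '<ann:hasPhysicalProperty rdf:resource="urn:old"/>'
            "</rdf:Description></rdf:RDF></model>"
        )
        (tmp_path / "m.ttl").write_text(
            "@prefix ann: <http://purl.org/modeldiscovery/annot#> .\n"
            "<m.cellml#C.v> ann:hasPhysicalProperty <urn:new> .\n"
        )
        from modeldiscovery.codec import load_corpus

        corpus, _ = load_corpus(tmp_path)
        anns = corpus.annotations_for("m.cellml#C.v")
        assert len(anns) == 1
        assert anns[0].property.uri == "urn:new"
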