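"""Ontology index, told-subsumption queries and axiom serialization."""

import networkx as nx
import pytest
from hypothesis import given, strategies as st
from rdflib import Graph

from termforge import fixtures as fx
from termforge import ontology as onto
from termforge.errors import UnknownEntityError
from termforge.patterns import And as PAnd, NamedRef


def _chain_index(n=5):
    spec = fx.FixtureSpec(seed=1, n_classes=n, shape="chain",
                          definition_fraction=0.0)
    return fx.index_from_manifest(fx._toy_manifest(spec))


class TestLoading:
    def test_chain_of_five_has_four_told_edges(self, tmp_path):
        spec = fx.FixtureSpec(seed=3, n_classes=5, shape="chain")
        manifest = fx.generate_toy_ontology(spec, tmp_path / "toy.ttl")
        idx = onto.load_ontology(tmp_path / "toy.ttl")
        assert len(idx.classes) == 5
        assert len(idx.told_subclass_edges) == 4
        assert idx.told_subclass_edges == set(manifest.edges)
        assert all(iri in idx.label_of for iri in idx.classes)

    def test_empty_document_yields_empty_index(self, tmp_path):
        path = tmp_path / "empty.ttl"
        path.write_text("", encoding="utf-8")
        idx = onto.load_ontology(path)
        assert not idx.classes and not idx.told_subclass_edges

    def test_missing_file_and_unknown_extension_rejected(self, tmp_path):
        with pytest.raises(onto.OntologyError):
            onto.load_ontology(tmp_path / "nope.ttl")
        bad = tmp_path / "x.dat"
        bad.write_text("", encoding="utf-8")
        with pytest.raises(onto.OntologyError):
            onto.load_ontology(bad)

    def test_label_collision_recorded_and_ambiguous(self):
        g = Graph()
        g.parse(data="""
            @prefix owl: <http://www.w3.org/2002/07/owl#> .
            @prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
            <http://x/a> a owl:Class ; rdfs:label "melanoma" .
            <http://x/b> a owl:Class ; rdfs:label "Melanoma" .
        """, format="turtle")
        idx = onto.build_index(g)
        assert len(idx.classes) == 2
        res = onto.label_lookup(idx, "melanoma")
        assert res.status is onto.ResolutionStatus.AMBIGUOUS
        assert set(res.candidates) == {"http://x/a", "http://x/b"}

    def test_label_priority_prefers_rdfs_label(self):
        g = Graph()
        g.parse(data="""
            @prefix owl: <http://www.w3.org/2002/07/owl#> .
            @prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
            @prefix skos: <http://www.w3.org/2004/02/skos/core#> .
            <http://x/a> a owl:Class ; rdfs:label "primary" ;
                skos:prefLabel "secondary" .
            <http://x/b> a owl:Class ; skos:prefLabel "fallback" .
        """, format="turtle")
        idx = onto.build_index(g)
        assert idx.label_of["http://x/a"] == "primary"
        assert idx.label_of["http://x/b"] == "fallback"


class TestLabelLookup:
    def test_exact_normalized_and_curie_lookup(self):
        idx = _chain_index()
        iri, label = next(iter(idx.label_of.items()))
        assert onto.label_lookup(idx, label).iri == iri
        assert onto.label_lookup(idx, f"  {label.upper()}  ").iri == iri
        assert onto.label_lookup(idx, iri).iri == iri
        assert onto.label_lookup(idx, f"<{iri}>").iri == iri
        curie = "toy:" + iri.split("/")[-1]
        idx.prefixes["toy"] = fx.TOY_NS
        assert onto.label_lookup(idx, curie).iri == iri

    def test_absent_label_not_found(self):
        idx = _chain_index()
        assert (onto.label_lookup(idx, "unicorn cell").status
                is onto.ResolutionStatus.NOT_FOUND)

    def test_lookup_never_returns_mismatched_label(self):
        idx = _chain_index(20)
        for iri, label in idx.label_of.items():
            res = onto.label_lookup(idx, label)
            assert res.found
            assert onto.normalize_label(idx.label_of[res.iri]) == \
                onto.normalize_label(label)


class TestDescendants:
    def test_top_class_returns_all_named_classes(self):
        idx = _chain_index()
        assert onto.descendants(idx, onto.OWL_THING) == idx.classes

    def test_leaf_has_no_descendants(self):
        idx = _chain_index()
        leaf = f"{fx.TOY_NS}C{4:05d}"
        assert onto.descendants(idx, leaf) == set()
        assert onto.descendants(
            idx, leaf, onto.QueryMode.SELF_AND_DESCENDANTS) == {leaf}

    def test_unknown_root_rejected(self):
        with pytest.raises(UnknownEntityError):
            onto.descendants(_chain_index(), "http://x/none")

    def test_cycles_tolerated_and_warned(self):
        g = Graph()
        g.parse(data="""
            @prefix owl: <http://www.w3.org/2002/07/owl#> .
            @prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
            <http://x/a> a owl:Class ; rdfs:subClassOf <http://x/b> .
            <http://x/b> a owl:Class ; rdfs:subClassOf <http://x/a> .
        """, format="turtle")
        idx = onto.build_index(g)
        assert any("cycle" in w for w in idx.warnings)
        assert onto.descendants(idx, "http://x/a") == {"http://x/a",
                                                       "http://x/b"}

    @given(st.integers(0, 500))
    def test_matches_brute_force_reachability_on_random_dags(self, seed):
        """Told closure equals independent graph-library reachability."""
        spec = fx.FixtureSpec(seed=seed, n_classes=30, shape="dag",
                              edge_prob=0.1)
        manifest = fx._toy_manifest(spec)
        idx = fx.index_from_manifest(manifest)
        g = nx.DiGraph()
        g.add_nodes_from(iri for iri, _ in manifest.classes)
        for sub, sup in manifest.edges:
            g.add_edge(sup, sub)  # parent -> child
        root = manifest.classes[seed % len(manifest.classes)][0]
        assert onto.descendants(idx, root) == nx.descendants(g, root)


class TestDLQueries:
    def test_conjunction_equals_closure_intersection(self):
        spec = fx.FixtureSpec(seed=11, n_classes=40, shape="dag",
                              edge_prob=0.15)
        manifest = fx._toy_manifest(spec)
        idx = fx.index_from_manifest(manifest)
        a, b = manifest.classes[0][0], manifest.classes[1][0]
        q = onto.DLQuery(PAnd((NamedRef(a), NamedRef(b))))
        expect = onto.descendants(idx, a) & onto.descendants(idx, b)
        assert onto.evaluate_dl_query(idx, q) == expect

    def test_top_query_and_disjoint_intersection(self):
        idx = _chain_index()
        q = onto.DLQuery(NamedRef("owl:Thing"))
        assert onto.evaluate_dl_query(idx, q) == idx.classes
        c3, c4 = f"{fx.TOY_NS}C{3:05d}", f"{fx.TOY_NS}C{4:05d}"
        # in a chain, descendants(C3)={C4}, descendants(C4)={} -> disjoint
        q2 = onto.DLQuery(PAnd((NamedRef(c3), NamedRef(c4))))
        assert onto.evaluate_dl_query(idx, q2) == set()

    def test_unsupported_query_form_rejected(self):
        idx = _chain_index()
        from termforge.patterns import parse_class_expression
        q = onto.DLQuery(parse_class_expression("a some b"))
        with pytest.raises(onto.OntologyError):
            onto.evaluate_dl_query(idx, q)


# --------------------------------------------------------------------------
# Axiom serialization round-trips
# --------------------------------------------------------------------------

_iris = st.from_regex(r"[a-z][a-z0-9]{0,6}", fullmatch=True).map(
    lambda s: f"http://example.org/termforge/gen/{s}")
_texts = st.text(alphabet=st.characters(min_codepoint=32, max_codepoint=126),
                 min_size=0, max_size=20)
_literals = st.builds(
    onto.OwlLiteral, text=_texts,
    lang=st.one_of(st.none(), st.just("en")),
    datatype=st.none())


def _ground_exprs():
    leaves = _iris.map(onto.Named)

    def extend(children):
        return st.one_of(
            st.tuples(_iris, children).map(lambda t: onto.SomeValues(*t)),
            st.tuples(_iris, children).map(lambda t: onto.OnlyValues(*t)),
            st.lists(children, min_size=2, max_size=3).map(
                onto.intersection_of),
            st.lists(children, min_size=2, max_size=3).map(onto.union_of),
            children.map(onto.ComplementOf))

    return st.recursive(leaves, extend, max_leaves=6)


_ground_axioms = st.one_of(
    st.tuples(_iris.map(onto.Named), _ground_exprs()).map(
        lambda t: onto.SubClassOf(*t)),
    st.tuples(_iris.map(onto.Named), _ground_exprs()).map(
        lambda t: onto.EquivalentClasses(*t)),
    st.tuples(_iris, _iris, _literals).map(
        lambda t: onto.AnnotationAssertion(*t)),
    st.tuples(_ground_exprs(), _iris).map(lambda t: onto.ClassAssertion(*t)),
    st.tuples(_iris, st.sampled_from(list(onto.EntityKind))).map(
        lambda t: onto.Declaration(*t)),
)


def _to_axiomset(axioms):
    out = onto.AxiomSet()
    for ax in axioms:
        out.add(ax)
    return out


class TestSerialization:
    @given(st.lists(_ground_axioms, max_size=12))
    def test_functional_syntax_round_trip(self, tmp_path_factory, axioms):
        axset = _to_axiomset(axioms)
        path = tmp_path_factory.mktemp("ofn") / "out.ofn"
        onto.serialize_axioms(axset, path, fmt="ofn")
        assert onto.load_axioms(path) == axset

    @given(st.lists(_ground_axioms, max_size=10))
    def test_turtle_round_trip(self, tmp_path_factory, axioms):
        axset = _to_axiomset(axioms)
        path = tmp_path_factory.mktemp("ttl") / "out.ttl"
        onto.serialize_axioms(axset, path, fmt="turtle")
        assert onto.load_axioms(path) == axset

    def test_output_is_deterministic(self, tmp_path):
        axset = _to_axiomset([
            onto.Declaration("http://x/b", onto.EntityKind.CLASS),
            onto.Declaration("http://x/a", onto.EntityKind.CLASS),
            onto.SubClassOf(onto.Named("http://x/a"),
                            onto.Named("http://x/b")),
        ])
        a, b = tmp_path / "a.ofn", tmp_path / "b.ofn"
        onto.serialize_axioms(axset, a)
        onto.serialize_axioms(axset, b)
        assert a.read_bytes() == b.read_bytes()
        lines = a.read_text().splitlines()
        assert lines[1].startswith("Declaration(Class(<http://x/a>")

    def test_empty_axiomset_is_valid_document(self, tmp_path):
        path = tmp_path / "empty.ofn"
        onto.serialize_axioms(onto.AxiomSet(), path)
        assert len(onto.load_axioms(path)) == 0

    def test_deduplication_keeps_all_provenance(self):
        axset = onto.AxiomSet()
        ax = onto.SubClassOf(onto.Named("http://x/a"),
                             onto.Named("http://x/b"))
        axset.add(ax, 1, "p1")
        axset.add(ax, 2, "p1")
        assert len(axset) == 1
        assert axset.provenance(ax) == [(1, "p1"), (2, "p1")]
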