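"""Ontology loading, disjointness derivation, Horn encoding, subsumption index."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alignrepair import (
    ClassRef,
    DisjointPair,
    InputError,
    OntologyGraph,
    PreconditionError,
    PropertyRestrictions,
    derive_disjointness,
    encode_horn,
    is_subsumed,
    load_ontology,
)


from conftest import OWL_BASE


def ref(iri: str, oid: int = 1) -> ClassRef:
    return ClassRef(iri, oid)


def oref(local: str) -> ClassRef:
    """Reference into a test OWL document (resolved against its base IRI)."""
    return ClassRef(OWL_BASE + local, 1)


def graph_from_edges(edges, oid: int = 1, extra=()) -> OntologyGraph:
    g = OntologyGraph(ontology_id=oid)
    for child, parent in edges:
        c, p = ref(child, oid), ref(parent, oid)
        g.classes.update((c, p))
        g.direct_sub.add((c, p))
    g.classes.update(ref(x, oid) for x in extra)
    return g.validate()


class TestTsvLoading:
    def test_fig1_blue_counts(self, fig1):
        o1, _, _ = fig1
        assert len(o1.classes) == 5
        assert len(o1.direct_sub) == 4
        assert len(o1.disjoints) == 1

    def test_empty_file(self, write_tsv):
        path = write_tsv("empty.tsv", "# nothing here\n")
        g = load_ontology(path, "tsv")
        assert not g.classes and not g.direct_sub and not g.disjoints

    def test_cycle_is_an_error(self, write_tsv):
        path = write_tsv("cyc.tsv", "SUB ex#A ex#B\nSUB ex#B ex#A\n")
        with pytest.raises(PreconditionError, match="cycle"):
            load_ontology(path, "tsv")

    def test_malformed_record(self, write_tsv):
        path = write_tsv("bad.tsv", "SUBCLASS ex#A ex#B\n")
        with pytest.raises(InputError, match="SUBCLASS"):
            load_ontology(path, "tsv")

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            load_ontology(tmp_path / "absent.tsv", "tsv")


class TestOwlLoading:
    def test_subclass_and_disjoint(self, write_owl):
        path = write_owl(
            "t.owl",
            """\
            <owl:Class rdf:about="ex#A"><rdfs:subClassOf rdf:resource="ex#B"/></owl:Class>
            <owl:Class rdf:about="ex#B"><owl:disjointWith rdf:resource="ex#C"/></owl:Class>
            <owl:Class rdf:about="ex#C"/>
            """,
        )
        g = load_ontology(path, "owl_rdfxml")
        assert {c.iri for c in g.classes} == {OWL_BASE + x for x in ("ex#A", "ex#B", "ex#C")}
        assert (oref("ex#A"), oref("ex#B")) in g.direct_sub
        assert {p.members() for p in g.disjoints} == {
            frozenset({oref("ex#B"), oref("ex#C")})
        }

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_all_disjoint_classes_expands_to_all_pairs(self, write_owl, n):
        members = "\n".join(f'<owl:Class rdf:about="ex#D{i}"/>' for i in range(n))
        path = write_owl(
            "adc.owl",
            f"""\
            <owl:AllDisjointClasses>
              <owl:members rdf:parseType="Collection">
            {members}
              </owl:members>
            </owl:AllDisjointClasses>
            """,
        )
        g = load_ontology(path, "owl_rdfxml")
        assert len(g.disjoints) == n * (n - 1) // 2

    def test_equivalent_intersection_gives_edges_and_multi_rule(self, write_owl):
        path = write_owl(
            "inter.owl",
            """\
            <owl:Class rdf:about="ex#C">
              <owl:equivalentClass>
                <owl:Class>
                  <owl:intersectionOf rdf:parseType="Collection">
                    <owl:Class rdf:about="ex#X"/>
                    <owl:Class rdf:about="ex#Y"/>
                  </owl:intersectionOf>
                </owl:Class>
              </owl:equivalentClass>
            </owl:Class>
            """,
        )
        g = load_ontology(path, "owl_rdfxml")
        assert (oref("ex#C"), oref("ex#X")) in g.direct_sub
        assert (oref("ex#C"), oref("ex#Y")) in g.direct_sub
        assert ((oref("ex#X"), oref("ex#Y")), oref("ex#C")) in g.intersection_axioms

    def test_owl_thing_is_excluded(self, write_owl):
        path = write_owl(
            "thing.owl",
            """\
            <owl:Class rdf:about="ex#A">
              <rdfs:subClassOf rdf:resource="http://www.w3.org/2002/07/owl#Thing"/>
            </owl:Class>
            """,
        )
        g = load_ontology(path, "owl_rdfxml")
        assert {c.iri for c in g.classes} == {OWL_BASE + "ex#A"}
        assert not g.direct_sub


class TestDerivedDisjointness:
    def test_incompatible_cardinalities(self):
        g = OntologyGraph(ontology_id=1)
        a, b = ref("ex#A"), ref("ex#B")
        g.classes.update((a, b))
        raw = PropertyRestrictions(
            cardinality={a: {"ex#p": (1, 1)}, b: {"ex#p": (2, 2)}}
        )
        pairs = derive_disjointness(g, raw)
        assert len(pairs) == 1
        (pair,) = pairs
        assert pair.provenance == "cardinality"
        assert pair.members() == frozenset({a, b})

    def test_overlapping_cardinalities_are_compatible(self):
        g = OntologyGraph(ontology_id=1)
        a, b = ref("ex#A"), ref("ex#B")
        g.classes.update((a, b))
        raw = PropertyRestrictions(
            cardinality={a: {"ex#p": (1, None)}, b: {"ex#p": (2, 3)}}
        )
        assert derive_disjointness(g, raw) == set()

    def test_functional_data_values(self):
        g = OntologyGraph(ontology_id=1)
        a, b, c = ref("ex#A"), ref("ex#B"), ref("ex#C")
        g.classes.update((a, b, c))
        raw = PropertyRestrictions(
            data_values={a: {"ex#q": "left"}, b: {"ex#q": "right"}, c: {"ex#q": "left"}}
        )
        pairs = derive_disjointness(g, raw)
        assert {p.members() for p in pairs} == {
            frozenset({a, b}),
            frozenset({b, c}),
        }
        assert all(p.provenance == "functional_data" for p in pairs)

    def test_object_property_fillers_need_declared_disjointness(self):
        g = OntologyGraph(ontology_id=1)
        a, b, f1, f2 = (ref(x) for x in ("ex#A", "ex#B", "ex#F1", "ex#F2"))
        g.classes.update((a, b, f1, f2))
        raw = PropertyRestrictions(
            object_fillers={a: {"ex#r": "ex#F1"}, b: {"ex#r": "ex#F2"}}
        )
        assert derive_disjointness(g, raw) == set()  # fillers not declared disjoint
        g.disjoints.add(DisjointPair(f1, f2))
        pairs = derive_disjointness(g, raw)
        derived = {p for p in pairs if p.provenance == "object_property"}
        assert {p.members() for p in derived} == {frozenset({a, b})}

    def test_from_owl_restrictions(self, write_owl):
        path = write_owl(
            "restr.owl",
            """\
            <owl:FunctionalProperty rdf:about="ex#q"/>
            <owl:Class rdf:about="ex#A">
              <rdfs:subClassOf><owl:Restriction>
                <owl:onProperty rdf:resource="ex#q"/>
                <owl:hasValue rdf:datatype="http://www.w3.org/2001/XMLSchema#string">v1</owl:hasValue>
              </owl:Restriction></rdfs:subClassOf>
            </owl:Class>
            <owl:Class rdf:about="ex#B">
              <rdfs:subClassOf><owl:Restriction>
                <owl:onProperty rdf:resource="ex#q"/>
                <owl:hasValue rdf:datatype="http://www.w3.org/2001/XMLSchema#string">v2</owl:hasValue>
              </owl:Restriction></rdfs:subClassOf>
            </owl:Class>
            """,
        )
        g = load_ontology(path, "owl_rdfxml")
        assert {(p.provenance, p.members()) for p in g.disjoints} == {
            ("functional_data", frozenset({oref("ex#A"), oref("ex#B")}))
        }

    def test_no_restrictions_no_pairs(self):
        g = OntologyGraph(ontology_id=1)
        assert derive_disjointness(g, PropertyRestrictions()) == set()


class TestHornEncoding:
    def test_chain_closure(self):
        g = graph_from_edges([("ex#A", "ex#B"), ("ex#B", "ex#C")])
        t = encode_horn(g)
        assert t.unary_rules == {
            (ref("ex#A"), ref("ex#B")),
            (ref("ex#B"), ref("ex#C")),
            (ref("ex#A"), ref("ex#C")),
        }

    def test_fig1_blue(self, fig1):
        o1, _, _ = fig1
        t = encode_horn(o1)
        expected = {
            (ref("fig1#D"), ref("fig1#C")),
            (ref("fig1#D"), ref("fig1#E")),
            (ref("fig1#F"), ref("fig1#C")),
            (ref("fig1#F"), ref("fig1#E")),
        }
        assert t.unary_rules == expected
        assert {p.members() for p in t.false_rules} == {
            frozenset({ref("fig1#E"), ref("fig1#G")})
        }

    def test_empty_graph(self):
        t = encode_horn(OntologyGraph(ontology_id=1))
        assert not t.unary_rules and not t.multi_rules and not t.false_rules

    def test_deterministic_and_idempotent(self, fig1):
        o1, _, _ = fig1
        assert encode_horn(o1) == encode_horn(o1)


class TestIsSubsumed:
    def test_fig1_examples(self, fig1):
        o1, _, _ = fig1
        assert is_subsumed(o1, ref("fig1#D"), ref("fig1#C"))
        assert is_subsumed(o1, ref("fig1#D"), ref("fig1#D"))  # reflexive
        assert not is_subsumed(o1, ref("fig1#C"), ref("fig1#D"))

    def test_unknown_class(self, fig1):
        o1, _, _ = fig1
        with pytest.raises(InputError):
            is_subsumed(o1, ref("fig1#D"), ref("fig1#missing"))

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=60))
    def test_agrees_with_fresh_reachability(self, seed, n):
        """The cached ancestor index must match a direct DFS on random DAGs."""
        rng = random.Random(seed)
        edges = []
        for child in range(1, n):
            for parent in rng.sample(range(child), min(child, rng.randint(1, 2))):
                edges.append((f"ex#N{child}", f"ex#N{parent}"))
        g = graph_from_edges(edges, extra=[f"ex#N{k}" for k in range(n)])
        adj: dict[str, list[str]] = {}
        for c, p in edges:
            adj.setdefault(c, []).append(p)

        def dfs_reaches(x: str, y: str) -> bool:
            stack, seen = [x], {x}
            while stack:
                cur = stack.pop()
                if cur == y:
                    return True
                for nxt in adj.get(cur, []):
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            return False

        pairs = [(rng.randrange(n), rng.randrange(n)) for _ in range(80)]
        for i, j in pairs:
            x, y = f"ex#N{i}", f"ex#N{j}"
            assert is_subsumed(g, ref(x), ref(y)) == dfs_reaches(x, y)


class TestDisjointPairInvariants:
    def test_canonical_order(self):
        p = DisjointPair(ref("ex#Z"), ref("ex#A"))
        assert (p.a.iri, p.b.iri) == ("ex#A", "ex#Z")

    def test_rejects_self_pair_and_cross_ontology(self):
        with pytest.raises(ValueError):
            DisjointPair(ref("ex#A"), ref("ex#A"))
        with pytest.raises(ValueError):
            DisjointPair(ref("ex#A", 1), ref("ex#B", 2))
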