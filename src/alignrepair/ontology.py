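"""Ontology model: class hierarchies, disjointness clauses and their Horn view.

An ontology is reduced to the part of its semantics that matters for
disjointness-based incoherence detection: named classes, the (acyclic)
subsumption relation between them, intersection axioms over named classes,
and clauses stating that two classes are disjoint.  Disjointness clauses are
drawn from four sources: explicit disjointness axioms, incompatible
cardinality restrictions on a shared data property, unequal value
restrictions on a shared functional data property, and value restrictions
with disjoint fillers on a shared functional object property.

The Horn view ``T(O)`` of an ontology contains a rule ``x -> y`` for every
distinct pair with ``x`` subsumed by ``y``, one multi-body rule per
intersection axiom, and one ``(x ∧ y) -> false`` clause per disjoint pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping as TMapping

import networkx as nx

from .errors import InputError, PreconditionError

logger = logging.getLogger(__name__)

#: IRIs that never discriminate coherence and are excluded from the model.
_EXCLUDED_IRIS = frozenset(
    {
        "http://www.w3.org/2002/07/owl#Thing",
        "http://www.w3.org/2002/07/owl#Nothing",
    }
)

PROVENANCES = ("syntactic", "cardinality", "functional_data", "object_property")


@dataclass(frozen=True, order=True)
class ClassRef:
    """A named class, identified by IRI, belonging to one input ontology."""

    iri: str
    ontology_id: int

    def __post_init__(self):
        if not self.iri:
            raise ValueError("class IRI must be non-empty")
        if self.ontology_id not in (1, 2):
            raise ValueError("ontology_id must be 1 or 2")


@dataclass(frozen=True)
class DisjointPair:
    """An unordered pair of same-ontology classes declared (or derived) disjoint."""

    a: ClassRef
    b: ClassRef
    provenance: str = "syntactic"

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("a disjoint pair must contain two distinct classes")
        if self.a.ontology_id != self.b.ontology_id:
            raise ValueError("disjoint classes must belong to the same ontology")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.b.iri < self.a.iri:  # store canonically, {a,b} is unordered
            first, second = self.b, self.a
            object.__setattr__(self, "a", first)
            object.__setattr__(self, "b", second)

    @property
    def key(self) -> tuple[ClassRef, ClassRef]:
        return (self.a, self.b)

    def members(self) -> frozenset[ClassRef]:
        return frozenset((self.a, self.b))


@dataclass
class PropertyRestrictions:
    """Per-class property-restriction facts extracted while loading an ontology.

    cardinality:      class -> data property IRI -> (min, max) interval,
                      with ``exactly k`` stored as ``(k, k)`` and absent
                      bounds as 0 / None.
    data_values:      class -> functional data property IRI -> required literal.
    object_fillers:   class -> functional object property IRI -> filler IRI
                      (a named class from a value restriction, or an
                      individual from a has-value restriction).
    filler_is_individual: (class, property) pairs whose filler is an individual.
    different_individuals: unordered IRI pairs declared pairwise different.
    """

    cardinality: dict[ClassRef, dict[str, tuple[int, int | None]]] = field(default_factory=dict)
    data_values: dict[ClassRef, dict[str, str]] = field(default_factory=dict)
    object_fillers: dict[ClassRef, dict[str, str]] = field(default_factory=dict)
    filler_is_individual: set[tuple[ClassRef, str]] = field(default_factory=set)
    different_individuals: set[frozenset[str]] = field(default_factory=set)

    def is_empty(self) -> bool:
        return not (self.cardinality or self.data_values or self.object_fillers)


@dataclass
class OntologyGraph:
    """One ontology's named classes, direct subsumptions and disjointness clauses.

    ``direct_sub`` holds ordered (child, parent) pairs; reachability over it
    is the subsumption relation.  The graph must be acyclic.  Instances are
    treated as immutable once validated; ancestor indexes are built lazily
    and cached.
    """

    ontology_id: int
    classes: set[ClassRef] = field(default_factory=set)
    direct_sub: set[tuple[ClassRef, ClassRef]] = field(default_factory=set)
    disjoints: set[DisjointPair] = field(default_factory=set)
    intersection_axioms: set[tuple[tuple[ClassRef, ...], ClassRef]] = field(default_factory=set)
    restrictions: PropertyRestrictions = field(default_factory=PropertyRestrictions)
    _ancestors: dict[ClassRef, frozenset[ClassRef]] | None = field(
        default=None, repr=False, compare=False
    )

    def validate(self) -> "OntologyGraph":
        """Check referential closure and acyclicity; raise on violation."""
        for child, parent in self.direct_sub:
            for c in (child, parent):
                if c not in self.classes:
                    raise InputError(f"subsumption references unknown class {c.iri}")
        for pair in self.disjoints:
            for c in (pair.a, pair.b):
                if c not in self.classes:
                    raise InputError(f"disjointness references unknown class {c.iri}")
        for body, head in self.intersection_axioms:
            for c in (*body, head):
                if c not in self.classes:
                    raise InputError(f"intersection axiom references unknown class {c.iri}")
        g = nx.DiGraph(self.direct_sub)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            names = " -> ".join(e[0].iri for e in cycle)
            raise PreconditionError(
                f"subsumption cycle detected in ontology {self.ontology_id}: {names}"
            )
        return self

    # -- subsumption index ------------------------------------------------

    def _build_index(self) -> dict[ClassRef, frozenset[ClassRef]]:
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        g.add_edges_from(self.direct_sub)
        anc: dict[ClassRef, frozenset[ClassRef]] = {}
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible as exc:  # pragma: no cover - validate() catches first
            raise PreconditionError("subsumption cycle detected") from exc
        succ = {n: list(g.successors(n)) for n in g}
        for node in reversed(order):
            acc: set[ClassRef] = set()
            for parent in succ[node]:
                acc.add(parent)
                acc |= anc[parent]
            anc[node] = frozenset(acc)
        return anc

    def ancestors(self, x: ClassRef) -> frozenset[ClassRef]:
        """All proper ancestors of ``x`` (classes that subsume it)."""
        if self._ancestors is None:
            object.__setattr__(self, "_ancestors", self._build_index())
        try:
            return self._ancestors[x]
        except KeyError:
            raise InputError(f"unknown class {x.iri} in ontology {self.ontology_id}") from None


@dataclass(frozen=True)
class HornTheory:
    """Horn-rule view of one or more ontologies, plus (optionally) an alignment.

    ``mapping_rules`` tags each alignment-derived unary rule with the mapping
    it came from, so conflict search can report sets of mappings rather than
    sets of rules.
    """

    unary_rules: frozenset[tuple[ClassRef, ClassRef]]
    multi_rules: frozenset[tuple[tuple[ClassRef, ...], ClassRef]]
    false_rules: frozenset[DisjointPair]
    mapping_rules: TMapping[tuple[ClassRef, ClassRef], object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# loading


def load_ontology(
    path: str | Path,
    dialect: str = "tsv",
    ontology_id: int = 1,
    derive: bool = True,
) -> OntologyGraph:
    """Load an ontology from ``path`` in the named dialect.

    ``dialect`` is ``"tsv"`` (the line-based hierarchy dialect used for
    fixtures) or ``"owl_rdfxml"``.  With ``derive=True`` (the default),
    disjointness clauses implied by property restrictions are added to the
    explicitly declared ones.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"ontology file not found: {path}")
    if dialect == "tsv":
        graph = _load_tsv(path, ontology_id)
    elif dialect == "owl_rdfxml":
        graph = _load_owl(path, ontology_id)
    else:
        raise InputError(f"unknown ontology dialect {dialect!r}")
    graph.validate()
    if derive and not graph.restrictions.is_empty():
        derived = derive_disjointness(graph, graph.restrictions)
        _merge_disjoints(graph, derived)
    return graph


def _merge_disjoints(graph: OntologyGraph, pairs: Iterable[DisjointPair]) -> None:
    seen = {p.key for p in graph.disjoints}
    for p in pairs:
        if p.key not in seen:
            graph.disjoints.add(p)
            seen.add(p.key)


def _load_tsv(path: Path, ontology_id: int) -> OntologyGraph:
    graph = OntologyGraph(ontology_id=ontology_id)

    def ref(iri: str) -> ClassRef:
        c = ClassRef(iri, ontology_id)
        graph.classes.add(c)
        return c

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            tag = fields[0].upper()
            if tag == "CLASS" and len(fields) == 2:
                ref(fields[1])
            elif tag == "SUB" and len(fields) == 3:
                graph.direct_sub.add((ref(fields[1]), ref(fields[2])))
            elif tag == "DIS" and len(fields) == 3:
                graph.disjoints.add(DisjointPair(ref(fields[1]), ref(fields[2])))
            else:
                raise InputError(f"{path}:{lineno}: unrecognized record {line!r}")
    return graph


_OWL = "http://www.w3.org/2002/07/owl#"
_RDFS = "http://www.w3.org/2000/01/rdf-schema#"


def _load_owl(path: Path, ontology_id: int) -> OntologyGraph:
    import rdflib
    from rdflib import RDF, RDFS, OWL
    from rdflib.collection import Collection

    g = rdflib.Graph()
    try:
        g.parse(str(path), format="xml")
    except Exception as exc:
        raise InputError(f"failed to parse OWL RDF/XML file {path}: {exc}") from exc

    graph = OntologyGraph(ontology_id=ontology_id)
    restr = graph.restrictions

    def named(node) -> ClassRef | None:
        if isinstance(node, rdflib.URIRef) and str(node) not in _EXCLUDED_IRIS:
            return ClassRef(str(node), ontology_id)
        return None

    for s in g.subjects(RDF.type, OWL.Class):
        c = named(s)
        if c is not None:
            graph.classes.add(c)
    for s in g.subjects(RDF.type, RDFS.Class):
        c = named(s)
        if c is not None:
            graph.classes.add(c)

    def intersection_members(node) -> tuple[ClassRef, ...] | None:
        inter = g.value(node, OWL.intersectionOf)
        if inter is None:
            return None
        members = []
        for item in Collection(g, inter):
            c = named(item)
            if c is None:
                return None
            members.append(c)
        return tuple(members) if members else None

    def register(c: ClassRef) -> ClassRef:
        graph.classes.add(c)
        return c

    functional = {str(p) for p in g.subjects(RDF.type, OWL.FunctionalProperty)}

    def handle_restriction(subject: ClassRef, node) -> bool:
        """Record a property restriction attached to ``subject``; True if handled."""
        if (node, RDF.type, OWL.Restriction) not in g:
            return False
        prop = g.value(node, OWL.onProperty)
        if prop is None:
            return False
        prop_iri = str(prop)
        card = g.value(node, OWL.cardinality)
        min_card = g.value(node, OWL.minCardinality)
        max_card = g.value(node, OWL.maxCardinality)
        if card is not None or min_card is not None or max_card is not None:
            lo = int(card) if card is not None else (int(min_card) if min_card is not None else 0)
            hi = int(card) if card is not None else (int(max_card) if max_card is not None else None)
            restr.cardinality.setdefault(subject, {})[prop_iri] = (lo, hi)
            return True
        has_value = g.value(node, OWL.hasValue)
        if has_value is not None:
            if isinstance(has_value, rdflib.Literal):
                if prop_iri in functional:
                    restr.data_values.setdefault(subject, {})[prop_iri] = str(has_value)
            else:
                if prop_iri in functional:
                    restr.object_fillers.setdefault(subject, {})[prop_iri] = str(has_value)
                    restr.filler_is_individual.add((subject, prop_iri))
            return True
        some = g.value(node, OWL.someValuesFrom)
        if some is not None:
            filler = named(some)
            if filler is not None and prop_iri in functional:
                restr.object_fillers.setdefault(subject, {})[prop_iri] = filler.iri
            return True
        return False

    for s, o in g.subject_objects(RDFS.subClassOf):
        cs, co = named(s), named(o)
        if cs is not None and co is not None:
            graph.direct_sub.add((register(cs), register(co)))
            continue
        if cs is not None:
            if handle_restriction(register(cs), o):
                continue
            members = intersection_members(o)
            if members is not None:
                # C ⊆ (x1 ∧ ... ∧ xn) contributes C -> xi for each conjunct
                for mcls in members:
                    graph.direct_sub.add((register(cs), register(mcls)))
                continue
            logger.warning("skipping complex superclass expression for %s", cs.iri)
            continue
        if co is not None:
            members = intersection_members(s)
            if members is not None:
                graph.intersection_axioms.add(
                    (tuple(register(m) for m in members), register(co))
                )
                continue
        logger.warning("skipping subclass axiom with unsupported expressions")

    for s, o in g.subject_objects(OWL.equivalentClass):
        cs, co = named(s), named(o)
        if cs is not None and co is None:
            members = intersection_members(o)
            if members is not None:
                # C ≡ (x1 ∧ ... ∧ xn): C -> xi plus the multi-body rule
                for mcls in members:
                    graph.direct_sub.add((register(cs), register(mcls)))
                graph.intersection_axioms.add(
                    (tuple(register(m) for m in members), register(cs))
                )
                continue
            logger.warning("skipping complex equivalent-class expression for %s", cs.iri)
        elif cs is not None and co is not None:
            # named ≡ named is a two-cycle under the subsumption encoding;
            # validate() will reject it, matching the acyclicity precondition
            graph.direct_sub.add((register(cs), register(co)))
            graph.direct_sub.add((register(co), register(cs)))

    for s, o in g.subject_objects(OWL.disjointWith):
        cs, co = named(s), named(o)
        if cs is not None and co is not None and cs != co:
            graph.disjoints.add(DisjointPair(register(cs), register(co)))

    for s in g.subjects(RDF.type, OWL.AllDisjointClasses):
        members_node = g.value(s, OWL.members)
        if members_node is None:
            continue
        refs = [named(i) for i in Collection(g, members_node)]
        refs = [r for r in refs if r is not None]
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                graph.disjoints.add(DisjointPair(register(refs[i]), register(refs[j])))

    for s in g.subjects(RDF.type, OWL.AllDifferent):
        members_node = g.value(s, OWL.distinctMembers) or g.value(s, OWL.members)
        if members_node is None:
            continue
        iris = [str(i) for i in Collection(g, members_node)]
        for i in range(len(iris)):
            for j in range(i + 1, len(iris)):
                restr.different_individuals.add(frozenset((iris[i], iris[j])))
    for s, o in g.subject_objects(OWL.differentFrom):
        restr.different_individuals.add(frozenset((str(s), str(o))))

    return graph


# ---------------------------------------------------------------------------
# derived disjointness


def _intervals_disjoint(a: tuple[int, int | None], b: tuple[int, int | None]) -> bool:
    (lo1, hi1), (lo2, hi2) = a, b
    if hi1 is not None and hi1 < lo2:
        return True
    if hi2 is not None and hi2 < lo1:
        return True
    return False


def derive_disjointness(
    o: OntologyGraph, raw_axioms: PropertyRestrictions
) -> set[DisjointPair]:
    """Disjoint pairs from explicit axioms plus incompatible property restrictions.

    Two classes are flagged disjoint when they carry non-overlapping
    cardinality intervals on a shared data property, unequal required values
    on a shared functional data property, or value restrictions on a shared
    functional object property whose fillers are themselves declared disjoint
    classes or pairwise-different individuals.
    """
    pairs: dict[tuple[ClassRef, ClassRef], DisjointPair] = {
        p.key: p for p in o.disjoints
    }

    def add(a: ClassRef, b: ClassRef, provenance: str) -> None:
        pair = DisjointPair(a, b, provenance)
        pairs.setdefault(pair.key, pair)

    declared_disjoint = {p.members() for p in o.disjoints}

    card = raw_axioms.cardinality
    for x in card:
        for y in card:
            if x.iri >= y.iri:
                continue
            for prop, iv_x in card[x].items():
                iv_y = card[y].get(prop)
                if iv_y is not None and _intervals_disjoint(iv_x, iv_y):
                    add(x, y, "cardinality")

    vals = raw_axioms.data_values
    for x in vals:
        for y in vals:
            if x.iri >= y.iri:
                continue
            for prop, vx in vals[x].items():
                vy = vals[y].get(prop)
                if vy is not None and vx != vy:
                    add(x, y, "functional_data")

    fillers = raw_axioms.object_fillers
    for x in fillers:
        for y in fillers:
            if x.iri >= y.iri:
                continue
            for prop, fx in fillers[x].items():
                fy = fillers[y].get(prop)
                if fy is None or fx == fy:
                    continue
                as_classes = frozenset(
                    (ClassRef(fx, o.ontology_id), ClassRef(fy, o.ontology_id))
                )
                as_individuals = frozenset((fx, fy))
                if (
                    as_classes in declared_disjoint
                    or as_individuals in raw_axioms.different_individuals
                ):
                    add(x, y, "object_property")

    return set(pairs.values())


# ---------------------------------------------------------------------------
# Horn encoding and subsumption queries


def encode_horn(o: OntologyGraph) -> HornTheory:
    """Encode ``o`` as a Horn theory: closed unary rules, intersection rules,
    and one false-clause per disjoint pair."""
    unary = set()
    for x in o.classes:
        for y in o.ancestors(x):
            if x != y:
                unary.add((x, y))
    return HornTheory(
        unary_rules=frozenset(unary),
        multi_rules=frozenset(o.intersection_axioms),
        false_rules=frozenset(o.disjoints),
    )


def is_subsumed(o: OntologyGraph, x: ClassRef, y: ClassRef) -> bool:
    """True iff ``x`` is subsumed by ``y`` (reflexively) in ``o``.

    Answered from the cached ancestor index, so repeated queries cost a set
    lookup rather than a graph traversal.
    """
    if x not in o.classes or y not in o.classes:
        unknown = x if x not in o.classes else y
        raise InputError(f"unknown class {unknown.iri} in ontology {o.ontology_id}")
    return x == y or y in o.ancestors(x)
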