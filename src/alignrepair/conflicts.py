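"""Enumeration of minimal conflicting mapping sets.

A conflict set is a subset-minimal set of mappings whose joint presence
makes some class reach both members of a disjointness clause in the merged
Horn theory of the two ontologies and the alignment.  Because conflict sets
are minimal, removing any single member resolves that incoherence, and a
repair is exactly a hitting set of the collection.

``find_conflict_sets`` is the production path: a label-propagating
breadth-first search over the core fragments that tracks, per reached
class, the antichain of subset-minimal mapping sets used to reach it.
``brute_force_conflicts`` is an independent oracle over the *full*
ontologies (subset enumeration plus closure) used in tests to validate the
fragment-based search; the two must agree on every instance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .alignment import Alignment, Mapping
from .errors import InputError, PreconditionError, SearchCapExceeded
from .modularization import Checkset, CoreFragment
from .ontology import ClassRef, DisjointPair, OntologyGraph


@dataclass(frozen=True)
class ConflictSet:
    """A minimal set of mappings that makes ``witness`` unsatisfiable by
    connecting it to both members of ``violated``."""

    mappings: frozenset[Mapping]
    witness: ClassRef
    violated: DisjointPair

    def __post_init__(self):
        if not self.mappings:
            raise ValueError("a conflict set must contain at least one mapping")

    def sort_key(self):
        return (
            sorted(m.key for m in self.mappings),
            self.witness.iri,
            self.violated.a.iri,
            self.violated.b.iri,
        )


@dataclass
class ConflictCollection:
    """All minimal conflicting mapping sets, in a canonical order."""

    sets: list[ConflictSet] = field(default_factory=list)

    @property
    def membership_count(self) -> dict[Mapping, int]:
        counts: dict[Mapping, int] = {}
        for cs in self.sets:
            for m in cs.mappings:
                counts[m] = counts.get(m, 0) + 1
        return counts

    def mapping_sets(self) -> set[frozenset[Mapping]]:
        return {cs.mappings for cs in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def _canonical(conflicts: dict[frozenset[Mapping], tuple[ClassRef, DisjointPair]]) -> ConflictCollection:
    """Apply global subset-minimality and normalize ordering."""
    minimal = [
        s for s in conflicts if not any(other < s for other in conflicts)
    ]
    sets = [
        ConflictSet(mappings=s, witness=conflicts[s][0], violated=conflicts[s][1])
        for s in minimal
    ]
    sets.sort(key=ConflictSet.sort_key)
    return ConflictCollection(sets=sets)


# ---------------------------------------------------------------------------
# production path: BFS over core fragments


def _insert_minimal(antichain: list[frozenset], candidate: frozenset) -> bool:
    """Insert ``candidate`` into an antichain of ⊆-minimal sets.

    Returns True if inserted; dominated supersets already present are
    removed in place.
    """
    for existing in antichain:
        if existing <= candidate:
            return False
    antichain[:] = [s for s in antichain if not candidate < s]
    antichain.append(candidate)
    return True


def _minimal_reach_sets(
    start: ClassRef,
    internal: dict[ClassRef, frozenset[ClassRef]],
    mapping_edges: dict[ClassRef, list[tuple[ClassRef, Mapping]]],
    cap: int,
) -> dict[ClassRef, list[frozenset[Mapping]]]:
    """For every class reachable from ``start``, the ⊆-minimal sets of
    mappings labelling a derivation ``start -> class``.

    Internal (within-fragment) subsumption steps carry no label; crossing a
    mapping adds it to the set.  Reachability is reflexive: ``start``
    itself is reached with the empty set.
    """
    reach: dict[ClassRef, list[frozenset[Mapping]]] = {start: [frozenset()]}
    queue: list[tuple[ClassRef, frozenset[Mapping]]] = [(start, frozenset())]
    while queue:
        node, used = queue.pop(0)
        if used not in reach.get(node, []):  # superseded by a smaller set
            continue
        targets: list[tuple[ClassRef, frozenset[Mapping]]] = []
        for anc in internal.get(node, frozenset()):
            targets.append((anc, used))
        for other, mapping in mapping_edges.get(node, ()):
            targets.append((other, used | {mapping}))
        for nxt, nxt_used in targets:
            antichain = reach.setdefault(nxt, [])
            if _insert_minimal(antichain, nxt_used):
                if len(antichain) > cap:
                    raise SearchCapExceeded(
                        f"more than {cap} minimal mapping sets for a single "
                        f"(witness, class) pair while searching from {start.iri}",
                        witness=start,
                    )
                queue.append((nxt, nxt_used))
    return reach


def find_conflict_sets(
    f1: CoreFragment,
    f2: CoreFragment,
    m: Alignment,
    cs: Checkset,
    max_sets_per_state: int = 10_000,
) -> ConflictCollection:
    """Enumerate all minimal conflicting mapping sets over the core fragments.

    The search starts from every checkset member and every relevant (mapped
    or disjoint) class — the latter are already fragment members and cover
    witnesses whose derivations branch at a mapped or disjoint class itself.
    Equivalence mappings are traversable in both directions, subsumption
    mappings in one.
    """
    internal: dict[ClassRef, frozenset[ClassRef]] = {}
    internal.update(f1.frag_sub)
    internal.update(f2.frag_sub)
    fragment_classes = f1.classes | f2.classes

    mapping_edges: dict[ClassRef, list[tuple[ClassRef, Mapping]]] = {}
    for mapping in m:
        for head, tail in mapping.rules():
            if head in fragment_classes and tail in fragment_classes:
                mapping_edges.setdefault(head, []).append((tail, mapping))

    pairs = sorted(
        f1.disjoints | f2.disjoints, key=lambda p: (p.a.iri, p.b.iri)
    )
    starts = sorted(cs.members | f1.relevant | f2.relevant, key=lambda c: (c.ontology_id, c.iri))

    found: dict[frozenset[Mapping], tuple[ClassRef, DisjointPair]] = {}
    for witness in starts:
        try:
            reach = _minimal_reach_sets(witness, internal, mapping_edges, max_sets_per_state)
        except SearchCapExceeded as exc:
            exc.partial = _canonical(found)
            raise
        for pair in pairs:
            sets_a = reach.get(pair.a)
            sets_b = reach.get(pair.b)
            if not sets_a or not sets_b:
                continue
            unions: list[frozenset[Mapping]] = []
            for sa, sb in itertools.product(sets_a, sets_b):
                _insert_minimal(unions, sa | sb)
            for u in unions:
                if not u:
                    raise PreconditionError(
                        f"class {witness.iri} is subsumed by both {pair.a.iri} and "
                        f"{pair.b.iri} without any mapping: ontology "
                        f"{pair.a.ontology_id} is individually incoherent"
                    )
                if u not in found:
                    found[u] = (witness, pair)
    return _canonical(found)


# ---------------------------------------------------------------------------
# test oracle: subset enumeration over the full ontologies


def _reflexive_ancestors(o: OntologyGraph) -> dict[ClassRef, frozenset[ClassRef]]:
    return {c: o.ancestors(c) | {c} for c in o.classes}


def brute_force_conflicts(
    o1: OntologyGraph,
    o2: OntologyGraph,
    m: Alignment,
    max_classes: int = 200,
    k: int = 4,
) -> ConflictCollection:
    """Exhaustively enumerate minimal incoherent mapping subsets of size ≤ k.

    Works on the full ontologies with no modularization, so it is an
    independent check of the fragment-based search.  Enumeration proceeds by
    increasing subset size, skipping supersets of sets already found
    incoherent, so each incoherent set reported is minimal.  Refuses inputs
    beyond ``max_classes`` total classes — this is a test oracle, not a
    production path.
    """
    n_total = len(o1.classes) + len(o2.classes)
    if n_total > max_classes:
        raise InputError(
            f"oracle refuses {n_total} classes (bound {max_classes}); "
            "it exists for small test instances only"
        )
    mappings = list(m)
    if o1.intersection_axioms or o2.intersection_axioms:
        checker = _ClosureChecker(o1, o2)
    else:
        checker = _CondensedChecker(o1, o2, mappings)

    found: dict[frozenset[Mapping], tuple[ClassRef, DisjointPair]] = {}
    for size in range(1, min(k, len(mappings)) + 1):
        for combo in itertools.combinations(mappings, size):
            subset = frozenset(combo)
            if any(prev <= subset for prev in found):
                continue
            hit = checker.incoherence_witness(subset)
            if hit is not None:
                found[subset] = hit
    return _canonical(found)


class _CondensedChecker:
    """Incoherence test over a condensed graph of mapping/disjoint endpoints.

    Per-ontology reachability between endpoints is precomputed once; testing
    a mapping subset then only requires transitive reach over a handful of
    condensed nodes.  A conflict exists iff two (possibly equal) endpoints
    of one ontology have a common subclass and reach the two members of a
    disjointness clause.
    """

    def __init__(self, o1: OntologyGraph, o2: OntologyGraph, mappings: list[Mapping]):
        self.pairs = sorted(o1.disjoints | o2.disjoints, key=lambda p: (p.a.iri, p.b.iri))
        nodes: set[ClassRef] = set()
        for mp in mappings:
            nodes.add(mp.source)
            nodes.add(mp.target)
        for p in self.pairs:
            nodes.add(p.a)
            nodes.add(p.b)
        self.nodes = nodes

        self.internal: dict[ClassRef, set[ClassRef]] = {n: set() for n in nodes}
        self.common_sub: set[frozenset[ClassRef]] = set()
        self.common_witness: dict[frozenset[ClassRef], ClassRef] = {}
        for o in (o1, o2):
            anc = _reflexive_ancestors(o)
            local = {n for n in nodes if n.ontology_id == o.ontology_id}
            for u in local:
                self.internal[u] = {v for v in local if v in anc[u]}
            for y in sorted(o.classes, key=lambda c: c.iri):
                rel = [u for u in local if u in anc[y]]
                for u, v in itertools.product(rel, rel):
                    key = frozenset((u, v))
                    if key not in self.common_sub:
                        self.common_sub.add(key)
                        self.common_witness[key] = y

    def incoherence_witness(
        self, subset: frozenset[Mapping]
    ) -> tuple[ClassRef, DisjointPair] | None:
        edges: dict[ClassRef, set[ClassRef]] = {n: set(self.internal[n]) for n in self.nodes}
        for mp in subset:
            for head, tail in mp.rules():
                edges[head].add(tail)
        reach: dict[ClassRef, set[ClassRef]] = {}
        for n in self.nodes:
            seen = {n}
            stack = [n]
            while stack:
                cur = stack.pop()
                for nxt in edges[cur]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            reach[n] = seen
        for pair in self.pairs:
            starters_a = [u for u in self.nodes if pair.a in reach[u]]
            starters_b = {u for u in self.nodes if pair.b in reach[u]}
            for u in starters_a:
                for v in starters_b:
                    if u.ontology_id != v.ontology_id:
                        continue
                    key = frozenset((u, v))
                    if key in self.common_sub:
                        return (self.common_witness[key], pair)
        return None


class _ClosureChecker:
    """Fallback oracle honouring multi-body (intersection) Horn rules.

    Runs a forward-chaining closure from every class for each tested subset;
    quadratic and only suitable for tiny handcrafted instances.
    """

    def __init__(self, o1: OntologyGraph, o2: OntologyGraph):
        self.o1, self.o2 = o1, o2
        self.pairs = sorted(o1.disjoints | o2.disjoints, key=lambda p: (p.a.iri, p.b.iri))
        self.base_edges: dict[ClassRef, set[ClassRef]] = {}
        for o in (o1, o2):
            for child, parent in o.direct_sub:
                self.base_edges.setdefault(child, set()).add(parent)
        self.multi = list(o1.intersection_axioms | o2.intersection_axioms)
        self.all_classes = sorted(o1.classes | o2.classes, key=lambda c: (c.ontology_id, c.iri))

    def _closure_from(self, start: ClassRef, edges: dict[ClassRef, set[ClassRef]]) -> set[ClassRef]:
        reached = {start}
        changed = True
        while changed:
            changed = False
            for cur in list(reached):
                for nxt in edges.get(cur, ()):
                    if nxt not in reached:
                        reached.add(nxt)
                        changed = True
            for body, head in self.multi:
                if head not in reached and all(b in reached for b in body):
                    reached.add(head)
                    changed = True
        return reached

    def incoherence_witness(
        self, subset: frozenset[Mapping]
    ) -> tuple[ClassRef, DisjointPair] | None:
        edges = {c: set(v) for c, v in self.base_edges.items()}
        for mp in subset:
            for head, tail in mp.rules():
                edges.setdefault(head, set()).add(tail)
        for y in self.all_classes:
            reached = self._closure_from(y, edges)
            for pair in self.pairs:
                if pair.a in reached and pair.b in reached:
                    return (y, pair)
        return None


# ---------------------------------------------------------------------------
# exact minimum hitting set (test oracle)


def minimum_hitting_set(collection: ConflictCollection) -> frozenset[Mapping]:
    """Smallest set of mappings intersecting every conflict set.

    Exact brute-force enumeration by increasing size over the mappings that
    occur in conflict sets; exponential in the worst case and intended as a
    test oracle for the greedy repair, not as a production path.
    """
    if len(collection) == 0:
        return frozenset()
    universe = sorted(
        {m for cs in collection for m in cs.mappings}, key=lambda m: m.key
    )
    sets = [cs.mappings for cs in collection]
    for size in range(1, len(sets) + 1):
        for combo in itertools.combinations(universe, size):
            chosen = frozenset(combo)
            if all(chosen & s for s in sets):
                return chosen
    return frozenset(universe)  # pragma: no cover - one per set always hits
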