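"""Global greedy alignment repair with optional confidence-based filtering.

The repair loop computes the core fragments and the collection of minimal
conflicting mapping sets once, then iteratively removes the mapping that
belongs to the most remaining conflict sets (ties broken by lowest
confidence, then lexicographically), deleting every conflict set the
removal resolves.  Since each conflict set is minimal, removing one member
resolves it, so the removed set is a hitting set of the collection and the
repaired alignment is coherent under the Horn encoding.

When a confidence threshold ε is supplied, the cardinality heuristic hands
over to a confidence-based filter once the best removal count drops below a
cardinality threshold: each not-yet-resolved conflict set removes its
lowest-confidence mapping w1 provided confidence(w1) + ε <
confidence(w2) − ε against the second lowest w2.  Filtering runs at most
once; surviving conflict sets fall back to the cardinality heuristic.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .alignment import Alignment, Mapping
from .conflicts import ConflictCollection, ConflictSet, find_conflict_sets
from .modularization import build_core_fragments
from .ontology import ClassRef, OntologyGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepairConfig:
    """Tunables of the repair loop.

    ``epsilon`` — confidence threshold ε in [0, 1); ``None`` disables
    filtering entirely.  ``cardinality_threshold`` — the removal count below
    which the cardinality heuristic is considered weakly discriminative and
    filtering takes over (the heuristic performs well empirically while
    removed mappings belong to more than ~10 conflict sets).
    """

    epsilon: float | None = None
    cardinality_threshold: int = 10

    def __post_init__(self):
        if self.epsilon is not None and not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must satisfy 0 <= epsilon < 1")
        if self.cardinality_threshold < 1:
            raise ValueError("cardinality_threshold must be >= 1")


@dataclass
class RepairResult:
    """Outcome of a repair run."""

    removed: list[Mapping]
    repaired: Alignment
    removed_by_filter: list[Mapping]
    residual_incoherent: int
    stats: dict = field(default_factory=dict)


def _tie_break_key(counts: dict[Mapping, int]):
    def key(m: Mapping):
        return (-counts[m], m.confidence, m.source.iri, m.target.iri)

    return key


def select_mapping_to_remove(
    c: ConflictCollection | list[ConflictSet],
    eps_prime: float | None,
    cfg: RepairConfig,
) -> Mapping | None:
    """The mapping in the most conflict sets; ties go to lowest confidence,
    then lexicographic (source IRI, target IRI).

    Returns ``None`` — signalling that filtering should take over — exactly
    when a confidence threshold below 1 is active and even the best removal
    would resolve fewer than ``cfg.cardinality_threshold`` conflict sets.
    """
    sets = list(c)
    counts: dict[Mapping, int] = {}
    for cs in sets:
        for m in cs.mappings:
            counts[m] = counts.get(m, 0) + 1
    if not counts:
        raise ValueError("select_mapping_to_remove requires a non-empty collection")
    best = min(counts, key=_tie_break_key(counts))
    if eps_prime is not None and eps_prime < 1 and counts[best] < cfg.cardinality_threshold:
        return None
    return best


def filter_conflicts(
    c: ConflictCollection | list[ConflictSet], eps: float
) -> set[Mapping]:
    """Confidence-based selection of mappings to remove (one filtering pass).

    Conflict sets are processed in *reverse* (descending) order of their
    lowest-confidence mapping: the set whose cheapest removal is most
    expensive goes first, and when its selected mapping also occurs in
    later sets those are resolved for free and skipped, which minimizes the
    number of selected mappings.  Sets already intersecting the accumulated
    removals are skipped.  From each remaining set the two lowest-confidence mappings
    ``w1 <= w2`` are taken and ``w1`` is selected iff
    ``confidence(w1) + eps < confidence(w2) - eps``; a singleton set has its
    sole mapping selected unconditionally, removal being its only
    resolution.
    """
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must satisfy 0 <= eps < 1")

    def lowest_conf(cs: ConflictSet) -> tuple:
        ranked = sorted(cs.mappings, key=lambda m: (m.confidence, m.key))
        return (ranked[0].confidence, ranked[0].key)

    ordered = sorted(list(c), key=lowest_conf, reverse=True)
    selected: set[Mapping] = set()
    for cs in ordered:
        if cs.mappings & selected:
            continue
        ranked = sorted(cs.mappings, key=lambda m: (m.confidence, m.key))
        w1 = ranked[0]
        if len(ranked) == 1:
            selected.add(w1)
            continue
        w2 = ranked[1]
        if w1.confidence + eps < w2.confidence - eps:
            selected.add(w1)
    return selected


def repair(
    o1: OntologyGraph,
    o2: OntologyGraph,
    m: Alignment,
    cfg: RepairConfig = RepairConfig(),
) -> RepairResult:
    """Repair ``m`` so that the merged Horn theory has no unsatisfiable class.

    Fragments and conflict sets are computed once; removal only ever deletes
    conflict sets, so recomputation is unnecessary.  With ``cfg.epsilon``
    set, a single confidence-filtering pass may replace greedy selection
    (see module docstring); afterwards ε' is raised to 1 so filtering never
    refires and the loop terminates.
    """
    t0 = time.perf_counter()
    f1, f2, checkset = build_core_fragments(o1, o2, m)
    collection = find_conflict_sets(f1, f2, m, checkset)

    eps_prime = cfg.epsilon
    remaining = list(collection)
    removed: list[Mapping] = []
    removed_by_filter: list[Mapping] = []
    iterations = 0
    while remaining:
        iterations += 1
        w = select_mapping_to_remove(remaining, eps_prime, cfg)
        if w is not None:
            removed.append(w)
            remaining = [cs for cs in remaining if w not in cs.mappings]
        else:
            filtered = filter_conflicts(remaining, eps_prime)
            if filtered:
                ordered = sorted(filtered, key=lambda mp: mp.key)
                removed.extend(ordered)
                removed_by_filter.extend(ordered)
                remaining = [cs for cs in remaining if not cs.mappings & filtered]
            else:
                logger.debug("filtering selected nothing; falling back to greedy")
            eps_prime = 1.0  # filtering never refires

    repaired = m.without(removed)
    residual, _ = incoherence_report(o1, o2, repaired)
    return RepairResult(
        removed=removed,
        repaired=repaired,
        removed_by_filter=removed_by_filter,
        residual_incoherent=residual,
        stats={
            "input_mappings": len(m),
            "conflict_sets": len(collection),
            "iterations": iterations,
            "removed": len(removed),
            "removed_by_filter": len(removed_by_filter),
            "fragment_sizes": [len(f1.classes), len(f2.classes)],
            "checkset_size": len(checkset),
            "runtime_s": time.perf_counter() - t0,
        },
    )


def incoherence_report(
    o1: OntologyGraph, o2: OntologyGraph, m: Alignment
) -> tuple[int, list[ClassRef]]:
    """Unsatisfiable classes of the merged Horn theory.

    A class is unsatisfiable when it reaches (reflexively) both members of
    some disjointness clause in the merged graph of both ontologies plus the
    mapping rules.  This is the Horn-encoding notion of incoherence; it is a
    lower bound on what a complete OWL reasoner would report, not a
    substitute for it.
    """
    import networkx as nx

    g = nx.DiGraph()
    for o in (o1, o2):
        g.add_nodes_from(o.classes)
        g.add_edges_from(o.direct_sub)
    for mapping in m:
        g.add_edges_from(mapping.rules())

    multi = list(o1.intersection_axioms | o2.intersection_axioms)
    pairs = sorted(o1.disjoints | o2.disjoints, key=lambda p: (p.a.iri, p.b.iri))
    witnesses: set[ClassRef] = set()
    if not multi:
        for pair in pairs:
            below_a = nx.ancestors(g, pair.a) | {pair.a}
            below_b = nx.ancestors(g, pair.b) | {pair.b}
            witnesses |= below_a & below_b
    else:
        # multi-body rules can fire along a derivation; fall back to
        # per-class forward chaining (small inputs only)
        edges = {n: set(g.successors(n)) for n in g}
        for y in g.nodes:
            reached = {y}
            changed = True
            while changed:
                changed = False
                for cur in list(reached):
                    for nxt in edges.get(cur, ()):
                        if nxt not in reached:
                            reached.add(nxt)
                            changed = True
                for body, head in multi:
                    if head not in reached and all(b in reached for b in body):
                        reached.add(head)
                        changed = True
            for pair in pairs:
                if pair.a in reached and pair.b in reached:
                    witnesses.add(y)
                    break
    ordered = sorted(witnesses, key=lambda c: (c.ontology_id, c.iri))
    return len(ordered), ordered
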