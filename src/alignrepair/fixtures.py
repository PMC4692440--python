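"""Deterministic synthetic instances and packaged toy fixtures.

``generate_instance`` emulates, at desk scale, the structure of the
biomedical matching problems the repair method targets: two DAG-shaped
class hierarchies (the second a structural copy of the first plus extra
classes, so that "correct" equivalence mappings between analogous classes
exist), a few disjointness clauses between unrelated classes, a mostly
correct alignment, and a fraction of planted wrong mappings that each
create a cross-ontology path to a disjoint pair.  Confidences are drawn
from a high band for correct mappings and a lower band for planted ones,
mirroring the assumption that matcher confidence correlates with
correctness.

The two packaged toy fixtures are reconstructions of small illustrative
instances: their edge lists satisfy every membership fact stated for them
(see the data files' comments) but are not unique reconstructions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

from .alignment import Alignment, Mapping, Relation, read_alignment
from .errors import InputError
from .ontology import ClassRef, DisjointPair, OntologyGraph, load_ontology


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic-instance generator (all counts, fully seeded)."""

    n1: int = 30
    n2: int = 30
    max_parents: int = 2
    depth: int = 5
    n_disjoint: int = 3
    n_mappings: int = 8
    p_conflict: float = 0.25
    conf_correct: tuple[float, float] = (0.85, 1.0)
    conf_wrong: tuple[float, float] = (0.4, 0.7)
    seed: int = 0

    def __post_init__(self):
        if min(self.n1, self.n2, self.n_disjoint, self.n_mappings) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.p_conflict <= 1.0:
            raise ValueError("p_conflict must lie in [0, 1]")
        if self.max_parents < 1 or self.depth < 1:
            raise ValueError("max_parents and depth must be positive")


def _random_dag(
    rng: random.Random, n: int, prefix: str, ontology_id: int, depth: int, max_parents: int
) -> OntologyGraph:
    """A layered random DAG: classes on ``depth`` levels, each non-root
    choosing 1..max_parents parents from strictly lower levels."""
    g = OntologyGraph(ontology_id=ontology_id)
    refs = [ClassRef(f"{prefix}#C{k:03d}", ontology_id) for k in range(n)]
    g.classes.update(refs)
    levels = [min(depth - 1, k * depth // max(n, 1)) for k in range(n)]
    for k, ref in enumerate(refs):
        if levels[k] == 0:
            continue
        pool = [r for j, r in enumerate(refs[:k]) if levels[j] < levels[k]]
        n_parents = rng.randint(1, min(max_parents, len(pool)))
        for parent in rng.sample(pool, n_parents):
            g.direct_sub.add((ref, parent))
    return g


def _copy_dag(
    src: OntologyGraph, rng: random.Random, n: int, prefix: str, depth: int, max_parents: int
) -> tuple[OntologyGraph, dict[ClassRef, ClassRef]]:
    """Structural copy of (a prefix of) ``src`` plus extra random classes."""
    g = OntologyGraph(ontology_id=2)
    originals = sorted(src.classes, key=lambda c: c.iri)[:n]
    twin = {c: ClassRef(f"{prefix}#C{i:03d}", 2) for i, c in enumerate(originals)}
    g.classes.update(twin.values())
    kept = set(originals)
    for child, parent in sorted(src.direct_sub, key=lambda e: (e[0].iri, e[1].iri)):
        if child in kept and parent in kept:
            g.direct_sub.add((twin[child], twin[parent]))
    for k in range(len(originals), n):
        ref = ClassRef(f"{prefix}#X{k:03d}", 2)
        g.classes.add(ref)
        pool = sorted(g.classes - {ref}, key=lambda c: c.iri)
        if pool:
            for parent in rng.sample(pool, rng.randint(1, min(max_parents, len(pool)))):
                g.direct_sub.add((ref, parent))
    return g, twin


def _sample_disjoints(
    rng: random.Random, o: OntologyGraph, count: int, tries: int = 400
) -> list[DisjointPair]:
    """Disjoint pairs between incomparable classes with no common descendant,
    so the ontology stays individually coherent."""
    classes = sorted(o.classes, key=lambda c: c.iri)
    if len(classes) < 2:
        if count > 0:
            raise InputError("not enough classes to place disjointness clauses")
        return []
    below: dict[ClassRef, set[ClassRef]] = {c: {c} for c in classes}
    for c in classes:
        for a in o.ancestors(c):
            below[a].add(c)
    pairs: list[DisjointPair] = []
    seen: set[frozenset[ClassRef]] = set()
    for _ in range(tries):
        if len(pairs) == count:
            break
        a, b = rng.sample(classes, 2)
        key = frozenset((a, b))
        if key in seen or below[a] & below[b]:
            continue
        seen.add(key)
        pairs.append(DisjointPair(a, b))
    if len(pairs) < count:
        raise InputError(
            f"could not place {count} disjoint pairs with empty common "
            f"descendants in ontology {o.ontology_id}"
        )
    return pairs


def _creates_incoherence(
    o1: OntologyGraph, o2: OntologyGraph, mappings: list[Mapping], candidate: Mapping
) -> bool:
    from .repair import incoherence_report

    count, _ = incoherence_report(o1, o2, Alignment(mappings + [candidate]))
    return count > 0


def generate_instance(p: GeneratorParams) -> tuple[OntologyGraph, OntologyGraph, Alignment]:
    """Generate a seeded repair instance (two ontologies plus an alignment).

    Postconditions, asserted before returning: both hierarchies are acyclic,
    each ontology is individually coherent, and with ``p_conflict == 0`` the
    merged theory is coherent as well (correct mappings that would
    accidentally conflict are filtered out during construction).
    """
    rng = random.Random(p.seed)
    o1 = _random_dag(rng, p.n1, "syn1", 1, p.depth, p.max_parents)
    o2, twin = _copy_dag(o1, rng, p.n2, "syn2", p.depth, p.max_parents)
    o1.validate()
    o2.validate()

    share1 = (p.n_disjoint + 1) // 2 if len(o1.classes) >= 2 else 0
    for pair in _sample_disjoints(rng, o1, min(share1, p.n_disjoint)):
        o1.disjoints.add(pair)
    for pair in _sample_disjoints(rng, o2, p.n_disjoint - len(o1.disjoints)):
        o2.disjoints.add(pair)

    wrong_slots = sum(rng.random() < p.p_conflict for _ in range(p.n_mappings))
    correct_slots = p.n_mappings - wrong_slots

    anc1 = {c: o1.ancestors(c) | {c} for c in o1.classes}
    mapped: list[Mapping] = []
    candidates = sorted(twin, key=lambda c: c.iri)
    rng.shuffle(candidates)
    for src in candidates:
        if len(mapped) == correct_slots:
            break
        conf = rng.uniform(*p.conf_correct)
        mapping = Mapping(src, twin[src], Relation.EQUIVALENCE, round(conf, 6))
        # keep only correct mappings that do not conflict with the ones so far
        if not _creates_incoherence(o1, o2, mapped, mapping):
            mapped.append(mapping)

    planted = _plant_conflicts(rng, o1, o2, twin, anc1, mapped, wrong_slots, p)
    alignment = Alignment(mapped + planted)

    _assert_preconditions(o1, o2)
    return o1, o2, alignment


def _plant_conflicts(
    rng: random.Random,
    o1: OntologyGraph,
    o2: OntologyGraph,
    twin: dict[ClassRef, ClassRef],
    anc1: dict[ClassRef, frozenset[ClassRef] | set[ClassRef]],
    correct: list[Mapping],
    slots: int,
    p: GeneratorParams,
) -> list[Mapping]:
    """Wrong mappings that, combined with one correct mapping, put some class
    below both members of a disjoint pair."""
    planted: list[Mapping] = []
    taken = {m.key for m in correct}
    correct_sources = {m.source for m in correct}
    anc2 = {c: o2.ancestors(c) | {c} for c in o2.classes}

    for _ in range(slots):
        options: list[Mapping] = []
        for pair in sorted(o1.disjoints, key=lambda q: (q.a.iri, q.b.iri)):
            for d1, d2 in ((pair.a, pair.b), (pair.b, pair.a)):
                # w: correct-mapped class subsumed (reflexively) by d2;
                # a: class subsumed by d1; the wrong mapping a ≍ twin(w)
                # makes a reach d2 through the correct mapping w ≍ twin(w)
                ws = [w for w in correct_sources if d2 in anc1[w]]
                alts = [a for a in o1.classes if d1 in anc1[a] and d2 not in anc1[a]]
                for w in sorted(ws, key=lambda c: c.iri):
                    for a in sorted(alts, key=lambda c: c.iri):
                        if (a.iri, twin[w].iri) not in taken:
                            options.append(
                                Mapping(a, twin[w], Relation.EQUIVALENCE, 0.0)
                            )
        for pair in sorted(o2.disjoints, key=lambda q: (q.a.iri, q.b.iri)):
            for d1, d2 in ((pair.a, pair.b), (pair.b, pair.a)):
                twins_below_d2 = [
                    m.source for m in correct if d2 in anc2[m.target]
                ]
                alts = [a for a in o2.classes if d1 in anc2[a] and d2 not in anc2[a]]
                for w in sorted(twins_below_d2, key=lambda c: c.iri):
                    for a in sorted(alts, key=lambda c: c.iri):
                        if (w.iri, a.iri) not in taken:
                            options.append(Mapping(w, a, Relation.EQUIVALENCE, 0.0))
        if not options:
            break  # no plantable conflict under these hierarchies
        choice = rng.choice(sorted(options, key=lambda m: m.key))
        conf = round(rng.uniform(*p.conf_wrong), 6)
        mapping = Mapping(choice.source, choice.target, choice.relation, conf)
        planted.append(mapping)
        taken.add(mapping.key)
    return planted


def _assert_preconditions(o1: OntologyGraph, o2: OntologyGraph) -> None:
    from .repair import incoherence_report

    o1.validate()
    o2.validate()
    count, witnesses = incoherence_report(o1, o2, Alignment())
    if count:
        raise AssertionError(
            f"generated ontologies are individually incoherent: {witnesses[:3]}"
        )


# ---------------------------------------------------------------------------
# packaged toy fixtures


def _fixture(onto1: str, onto2: str, align: str):
    base = resources.files("alignrepair") / "data"
    with resources.as_file(base / onto1) as p1:
        o1 = load_ontology(p1, "tsv", ontology_id=1)
    with resources.as_file(base / onto2) as p2:
        o2 = load_ontology(p2, "tsv", ontology_id=2)
    with resources.as_file(base / align) as pa:
        m = read_alignment(pa, "tsv", o1, o2)
    return o1, o2, m


def fig1_fixture() -> tuple[OntologyGraph, OntologyGraph, Alignment]:
    """The two-toy-ontology worked example.

    Blue side {C, D, E, F, G} with D, F each under C and E and E disjoint
    from G; green side {I, J} with J under I; equivalence mappings C ≍ J
    (0.8) and G ≍ I (0.6).  D is unsatisfiable: it sits directly under E and
    reaches G through the two mappings.  Reconstructed topology (see data
    file comments).
    """
    return _fixture("fig1_onto1.tsv", "fig1_onto2.tsv", "fig1_alignment.tsv")


def fig2_fixture() -> tuple[OntologyGraph, OntologyGraph, Alignment]:
    """Desk-scale reconstruction of a real conflicting mapping pair between
    anatomy thesauri: "surface of cell" lies under "anatomical surface",
    which is disjoint from "cardinal cell part", while the two mappings
    identify "cardinal cell part" with "cell part" and "surface of cell"
    with "cell surface" (itself under "cell part")."""
    return _fixture("fig2_onto1.tsv", "fig2_onto2.tsv", "fig2_alignment.tsv")
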