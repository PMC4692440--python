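# alignrepair

Coherence repair of ontology alignments through core-fragment
modularization, minimal conflict-set enumeration, and a global greedy
removal heuristic with optional confidence-based filtering.

## The problem

Ontology matching produces an *alignment* `M`: a set of mappings, each
linking a class of ontology `O₁` to a class of ontology `O₂` with a
relation (equivalence `≍` or subsumption `⊆`) and a confidence in [0, 1].
For large biomedical ontologies (anatomy and cancer thesauri, clinical
terminologies), automatically produced alignments are routinely *logically
incoherent*: the union `O₁ ∪ O₂ ∪ M` entails that some class is
unsatisfiable, typically because mappings connect it to both members of a
disjointness constraint. An *alignment repair* is a subset `R ⊆ M` whose
removal restores coherence; under the minimal-impact paradigm a good repair
removes as few (and as dubious) mappings as possible.

`alignrepair` is aimed at ontology-matching practitioners who need to audit
or repair class-level alignments without running a full OWL reasoner over
merged hundred-thousand-class ontologies.

## The method

Each ontology is encoded as a Horn propositional theory `T(O)`:

* `x → y` for all distinct classes with `x ⊆ y`,
* `(x₁ ∧ … ∧ xₙ) → y` for each intersection axiom,
* `(x ∧ y) → false` for each disjoint pair — taken from explicit
  disjointness axioms and from incompatible cardinality / functional data /
  functional object property restrictions.

Mappings add `x → y` (subsumption) or `x → y, y → x` (equivalence;
equivalence mappings are indivisible units). A class is unsatisfiable when
it reaches both members of a disjoint pair in `T(O₁ ∪ O₂ ∪ M)`.

The pipeline:

1. **Modularization.** Extract per ontology a *core fragment*: the classes
   occurring in mappings or disjoint pairs (`Cᵢ`), one representative per
   group of classes sharing a maximal distinct `Cᵢ`-ancestor signature (the
   *checkset* — the classes that must be tested for unsatisfiability), and
   the subsumption closure restricted to those classes. Every minimal
   conflict detectable on the full ontologies is detectable on the
   fragments, which are typically a few percent of the input size.
2. **Conflict enumeration.** A breadth-first search from each checkset and
   relevant class over the fragments, tracking the subset-minimal sets of
   mappings used to reach each class, yields all minimal *conflict sets* —
   sets of mappings that jointly make some class unsatisfiable.
3. **Repair.** The minimum hitting set over conflict sets is NP-complete,
   so a greedy heuristic iteratively removes the mapping in the most
   remaining conflict sets (ties: lowest confidence, then lexicographic).
   With a confidence threshold ε, once the best removal count falls below a
   cardinality threshold, one filtering pass instead removes each
   unresolved set's lowest-confidence mapping `w₁` when
   `conf(w₁) + ε < conf(w₂) − ε` against the runner-up `w₂`.

## Worked example

The packaged toy instance has a blue ontology {C, D, E, F, G} (D, F below
both C and E; E disjoint from G), a green ontology {J ⊆ I}, and mappings
C ≍ J (0.8) and G ≍ I (0.6). D is unsatisfiable: it is a direct subclass
of E and reaches G through the two mappings.

```python
from alignrepair import fig1_fixture, repair

o1, o2, m = fig1_fixture()
result = repair(o1, o2, m)
print("removed:", [(mp.source.iri, mp.target.iri, mp.confidence) for mp in result.removed])
print("stats:", {k: v for k, v in result.stats.items() if k != "runtime_s"})
```

prints

```
removed: [('fig1#G', 'fig1#I', 0.6)]
stats: {'input_mappings': 2, 'conflict_sets': 1, 'iterations': 1, 'removed': 1,
        'removed_by_filter': 0, 'fragment_sizes': [4, 2], 'checkset_size': 1}
```

The fragments keep 6 of the 7 classes, the checkset is the single class D,
there is one conflict set containing both mappings, and the repair removes
the lower-confidence one; the repaired alignment has no unsatisfiable
class.

The same pipeline is available from the shell. On a generated synthetic
instance (two 30-class hierarchies, 8 mappings, ~40 % planted conflicts):

```bash
alignrepair simulate --seed 5 --p-conflict 0.4 --out-dir work/
alignrepair repair --onto1 work/onto1.tsv --onto2 work/onto2.tsv \
    --alignment work/alignment.tsv --out work/repaired.tsv --epsilon 0.05
```

```json
{
  "input_mappings": 8,
  "conflict_sets": 3,
  "removed": 3,
  "removed_by_filter": 3,
  "residual_incoherent": 0,
  "fragment_sizes": [9, 7],
  "checkset_size": 2
}
```

All three conflicts were resolved by the filtering pass (each involved one
clearly lower-confidence planted mapping) and the result is coherent.
Other subcommands: `modularize` (fragment/checkset membership),
`conflicts` (the minimal conflict sets as JSON), `check` (unsatisfiable
class count of any ontology pair + alignment), each accepting OWL RDF/XML
(`--onto-format owl`) or the TSV fixture dialect, and the INRIA Alignment
Format (`--align-format rdf`) or TSV alignments.

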