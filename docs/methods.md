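# Methods

## Model and assumptions

The package works on a propositional Horn abstraction of each ontology:
named classes, the acyclic subsumption relation between them, intersection
axioms over named classes, and binary disjointness clauses. Four sources
feed the disjointness clauses: explicit disjointness axioms (n-ary axioms
are expanded into all n(n−1)/2 pairs); non-overlapping cardinality
intervals on a shared data property (`exactly k` is the interval [k, k],
a missing bound is 0 or ∞, incompatibility is empty interval
intersection); unequal required values on a shared functional data
property; and value restrictions on a shared functional object property
whose fillers are themselves declared disjoint classes or
pairwise-different individuals. The object-property rule is deliberately
conservative — it only fires on declared filler disjointness/distinctness,
so it cannot invent disjointness that the input does not support.

Standing preconditions, checked and reported as errors rather than
repaired: each input ontology is individually coherent, and its subsumption
relation is acyclic. A pair of named classes declared mutually equivalent
inside one ontology is a subsumption 2-cycle under this encoding and is
therefore rejected; condensing such cycles is out of scope. `owl:Thing`
and `owl:Nothing` are excluded from the class set — they never
discriminate coherence.

Subsumption closure is computed syntactically from asserted named-class
axioms (subclass edges, plus the per-conjunct edges contributed by
equivalences with intersections of named classes); no description-logic
reasoner is invoked, and complex class expressions other than
intersections of named classes are skipped with a warning. Consequently
the incoherence notion used throughout — a class reaching, reflexively,
both members of a disjoint pair in the merged rule graph — is a *lower
bound* on what a complete OWL reasoner would report.

## Core fragments and the checkset

The relevant classes `Cᵢ` of ontology i are those occurring in a mapping
or a disjointness clause. Checkset candidates are classes with at least
two distinct proper `Cᵢ`-ancestors; candidates are grouped by their full
`Cᵢ`-ancestor signature, groups whose signature is a strict subset of
another candidate's are dropped (the larger-signature representative
reaches every relevant ancestor of the dropped class without crossing any
mapping, hence witnesses every conflict the dropped class would), and one
representative per surviving group is kept — the lexicographically
smallest IRI, purely so that runs are reproducible; any member of the
group is equally valid, and a dedicated test swaps the representative and
checks that nothing observable changes. When both endpoints of an
equivalence mapping qualify, the ontology-2 endpoint is dropped: each
endpoint of an equivalence reaches exactly what the other reaches in the
merged theory, so one suffices.

The fragment of ontology i is `Cᵢ` plus its checkset members, with the
full ontology's subsumption closure restricted to those classes (a
restricted transitive closure, not a reduction: queries inside the
fragment must coincide exactly with subsumption in the full ontology).

One design point was genuinely open: candidacy based on *proper* ancestors
leaves witnesses uncovered whose two derivations branch at a mapped or
disjoint class itself — for example, a mapped class lying directly under
one disjoint class, as in the packaged anatomy-thesaurus toy instance,
where the checkset is empty yet a conflict exists. The conflict search
therefore starts its traversals from the checkset members *and* from every
relevant class. Relevant classes are fragment members anyway, so the
additional cost is marginal, and the suite-wide equivalence tests against
the exhaustive oracle confirm that this combination misses nothing on the
instance family exercised.

## Conflict enumeration

For each start class the search propagates, through fragment subsumption
edges (label-free) and mapping edges (labelled with their mapping;
equivalences traversable both ways), the antichain of subset-minimal
mapping sets that reach each class. For every disjoint pair reachable on
both sides, the minimal unions of one set per side are conflict-set
candidates; global subset-minimality is then applied across all witnesses
and pairs, and the collection is sorted canonically (by mapping keys, then
witness IRI) so identical inputs yield identical output, including order.

An empty minimal union means the start class reaches both members of a
disjoint pair without any mapping — an individually incoherent input,
reported as a precondition violation.

The per-(start, class) antichain is capped (default 10 000 minimal sets);
exceeding the cap raises an explicit error carrying the partial collection
rather than silently truncating, because downstream guarantees (the
repaired alignment is coherent) rest on the enumeration being complete.

Multi-body intersection rules are not traversed by the fragment search:
the fragment construction and its correctness argument are stated over
unary subsumption paths. The exhaustive oracle does honour them (via
forward-chaining closure), so instances where an intersection rule
participates in an incoherence would surface as an oracle/search
divergence rather than pass silently; the synthetic generator emits no
intersection axioms.

## Repair loop

Conflict sets are computed once. Removing a mapping only ever deletes
conflict sets (a set's conflict-hood does not depend on which other
mappings are present), so recomputation after each removal is unnecessary.
Greedy selection removes the mapping in the most remaining sets; ties are
broken by lowest confidence, then by (source IRI, target IRI) — the final
tie-break exists only for determinism.

Filtering parameters, with defaults and rationale:

* `epsilon` (ε, dimensionless confidence margin, default absent): a
  mapping is only filtered out when its confidence is more than 2ε below
  the set's runner-up, i.e. when confidence is genuinely discriminative.
  Absent ε disables filtering entirely and the loop is purely greedy.
  Matcher confidence scales differ, so no universal default is sensible;
  0.05 is used throughout the test suites.
* `cardinality_threshold` (conflict-set count, default 10): the greedy
  count heuristic is empirically informative while removals resolve many
  sets at once; below the threshold (and only when ε is given) selection
  returns null and one filtering pass runs instead.

The filtering pass processes conflict sets in *descending* order of their
lowest-confidence mapping and skips sets already hit by an accumulated
removal. Descending order minimizes the number of selected mappings: the
set whose cheapest removal is most expensive goes first, and when its
selection also occurs in later (cheaper) sets, those resolve for free.
A singleton conflict set has its sole mapping selected unconditionally —
removing it is the only possible resolution. After one pass ε′ is raised
to 1, which permanently disables the null-return of greedy selection, so
filtering never refires and the loop terminates even when the pass
selected nothing.

Removal order within one filtering pass is sorted by mapping key; the
`removed` list of a run is therefore a deterministic function of inputs
and configuration. The repaired alignment always intersects every
pre-repair conflict set (hitting-set property), hence reports zero
unsatisfiable classes under the Horn encoding.

## Test oracles

Two independent oracles back the implementation-level tests:

* `brute_force_conflicts` enumerates mapping subsets by increasing size
  (skipping supersets of sets already found incoherent, so reported sets
  are minimal) over the **full** ontologies, deciding each subset via a
  condensed reachability graph over mapping/disjoint endpoints with
  per-ontology ancestor sets precomputed once — an algorithmic route
  sharing nothing with the fragment search. The default size bound is 4;
  the equivalence suites call it with the bound set to the alignment size
  so the comparison is a strict set equality, not a truncated one.
* `minimum_hitting_set` finds the exact optimum by enumeration over the
  mappings occurring in conflict sets, by increasing size. It is
  exponential and exists purely to measure the greedy heuristic's
  optimality gap at test scale.

## Synthetic generator

`generate_instance` emulates the repair-relevant structure of real
matching problems: ontology 2 is a structural copy of ontology 1 (plus
extra randomly attached classes), so "correct" mappings link structurally
analogous classes; disjoint pairs are placed between incomparable classes
with no common descendant (individual coherence by construction, asserted
before returning); planted wrong mappings each combine with one correct
mapping to put some class below both members of a disjoint pair.
Correct-mapping confidences are drawn uniformly from [0.85, 1.0] and
planted ones from [0.4, 0.7], a separation wide enough that filtering has
discriminative cases while remaining within realistic matcher output;
each mapping is planted-wrong independently with probability `p_conflict`.
Correct mappings that would accidentally create an incoherence (possible
because the copy gains extra classes) are dropped during construction, so
`p_conflict = 0` yields a coherent instance by contract.

What the generator does **not** emulate: lexical class labels and
near-synonym noise, intersection axioms, property restrictions (derived
disjointness is exercised by handcrafted inputs instead), subsumption
mappings in the alignment (planted mappings are equivalences, as are the
vast majority of real matcher outputs), and scale. Passing suites
therefore demonstrate correctness of the algorithms under the Horn
abstraction, not end-to-end quality on full-size biomedical ontologies.

The randomized suites run 200 instances (hierarchies of 20–60 classes per
side, 4–12 mappings, 1–4 disjoint pairs, planted-conflict rates 0.2–0.6)
for the fragment/oracle equivalence and coherence checks and the first 100
of them for the optimality-gap measurement — sizes chosen so the
exhaustive oracles stay exact while the suite still exercises hundreds of
distinct conflict topologies.

## Known limitations

* Coherence is with respect to the Horn encoding; a DL reasoner can report
  additional unsatisfiable classes (non-disjointness restrictions, complex
  expressions). The `check` subcommand labels its output accordingly.
* Property (relation) mappings, instance data, EDOAL complex
  correspondences, and altering mapping relations (e.g. weakening an
  equivalence to a subsumption) are out of scope; repair is removal-only.
* The OWL reader handles RDF/XML with the constructs listed above;
  anything else is skipped with a warning rather than reasoned over.
* The exact-repair and exhaustive-conflict routines are test oracles with
  hard input bounds, not production paths.
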