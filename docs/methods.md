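# Methods

## Model class and semantics

A logical model is `M = (V, f)` with components `c ∈ V`, levels
`0..max_level(c)` (`max_level = 1` Boolean, `2` ternary, …) and one rule
`f_c` per component.  Rules are ordered `(condition, target_level)` cases
over threshold atoms `X:k` (true iff the level of `X` is ≥ `k`), combined
with NOT/AND/OR and the constants 0/1; the target of a state is the target
level of the first satisfied case, 0 if none.  Boolean components carry a
single case with target 1, which makes the bnet `target, factors` line
format and the case machinery coincide.

Dynamics are stepwise: a component moves at most one level per update
toward its target.  This is the standard convention for multivalued
logical models (for Boolean components it changes nothing); it matters for
trap-space closure, where a component can only leave a hypercube through
an adjacent level.

*Input convention.*  A component whose rule is exactly itself (`A, A`), or
flagged `input` in the JSON dialect, is an input.  Inputs are excluded
from all impact tallies: an unclamped input trivially stays free, and a
clamped input is part of the imposed context rather than an effect of it.

*Regulators* `R(c)` are exactly the components appearing in atoms of
`f_c` — a purely syntactic notion, deliberately, since sub-model
extraction and graph export follow the rule text, not its semantics.

## Value propagation

Given clamps (a partial assignment that *overrides* the clamped
components' rules — mutant semantics), propagation runs a worklist
fixpoint: whenever the rule of a free component simplifies to a constant
under the current frozen assignment, the component freezes there and its
targets are re-examined.  Each component freezes at most once, so the loop
terminates in at most `|V|` freezes; because a rule constant under an
assignment stays constant (at the same value) under any extension, the
result is independent of worklist order.  The test suite checks this
confluence explicitly by shuffling the worklist.

**Constancy is decided semantically**, by exhaustive evaluation of the
constant-folded rule over all combinations of its remaining free
regulators, not by algebraic rewriting.  Folding alone misses rules such
as `A | !A`; exhaustive evaluation is complete, and its cost is bounded by
the rule's in-degree, which is small in curated models.  Residual rules of
free components are reported constant-folded but not otherwise minimised —
only constancy matters for freezing, and the folded form stays close to
what the modeller wrote.

The frozen assignment of a propagation is always a trap space of the
clamped model, and every stable state of the clamped model agrees with it;
both facts are verified against brute-force oracles on seeded random
models.  At small scale the suite also checks the stronger reduction
property: stable states of the residual model over free components,
extended by the frozen values, are exactly the stable states of the
clamped model.

*Differential comparison.*  Two propagation results are compared
per-component into categories (frozen OFF/ON in both at the same level,
frozen in both at different levels, frozen on one side only, free in
both), with a 3×3 tally (frozen-inactive / frozen-active / free × A / B /
intersection) over non-input components.  The A and B columns each sum to
the number of non-input components; the intersection column counts only
components frozen identically in both analyses or free in both, so it
generally sums to less — components frozen on one side only belong to no
intersection row.  "Frozen active" means frozen at level ≥ 1, so a ternary
component frozen at 1 or 2 counts the same.  The annotated regulatory
graph (DOT, or GraphML via networkx) colors nodes by category: inputs
gray, both-OFF yellow, both-ON orange, A-only OFF light blue, A-only ON
dark blue, B-only frozen green shades, free white.

## Sub-model extraction

`S = C ∪ ⋃_{c∈C} R(c)`; for each kept component, the original rule is
retained iff all its regulators are in `S`, otherwise the component
becomes a self-input.  Exactly one regulator layer is added — no
transitive closure — and boundary components become *inputs* rather than
constants, so the verification harness can explore every boundary
valuation.  A non-selected component whose regulators all happen to lie in
`S` keeps its rule; no special case.  The operation is idempotent on the
same selection.

## Stable states and trap spaces

*Stable states* (`f(x) = x`) are enumerated completely by depth-first
search over component assignments in declaration order, using propagation
as a constraint propagator: each branch percolates, branches in which some
frozen component's own rule is constant at a different value are pruned
(sound: constancy over a subspace forces the value in every stable state
of that subspace), and full leaves are verified exactly.  Output is
lexicographic in declaration order, for reproducible reports.

*Trap spaces* are subspaces fixing some components at single levels and
leaving the rest unrestricted.  With stepwise dynamics, a subspace is
closed iff every fixed component's rule is constant at its fixed level
over the subspace — the same constancy test propagation uses.  Minimal
(most-specific) trap spaces are found by a branch-and-prune search:
candidates are closed under value percolation (any minimal trap space is),
contradicted fixings are pruned, candidates with a fixed component whose
rule is not yet constant branch on that component's free regulators, and
recorded trap spaces are further refined to find smaller ones inside;
memoisation on the percolated candidate bounds the search, and a final
pass filters non-minimal entries.  This keeps the package free of external
constraint solvers; the intended problem sizes are the small sub-models
used in verification, while the large-model workflow needs only
propagation and stable states.  Both searches are validated against
exhaustive oracles (`2^n` states; `3^n` subspaces Boolean) that go through
the one-step successor relation only.

*Multivalued handling.*  The trap-space search runs directly on
multivalued models — the constancy test is level-aware, so no encoding is
needed.  A separate Booleanization (threshold-indicator / van Ham mapping)
is provided: a level-`ℓ` component becomes indicators `c_b1..c_bℓ`
(`c_bk` ≡ level ≥ k), with rules
`c_bk = (f≥k ∧ c_b(k−1)) ∨ c_b(k+1)` so that updates preserve indicator
monotonicity and mimic one-level steps.  Inadmissible states are never
stable under this encoding, and stable states of the encoding correspond
bijectively to those of the multivalued model — checked both ways by
brute force on random multivalued models.

## Verification harness

A specification couples a context (clamps — inputs and perturbations are
the same mechanism) with expected activities (`active` ≡ level ≥ 1,
`inactive` ≡ level 0, or `level=k`), an oracle (`stable_states`,
`trap_spaces`, `propagation`) and a quantifier (`all`/`exists`).  The
default oracle is minimal trap spaces with `all`: trap spaces cover cyclic
behaviour that stable states miss, and every stable state is itself a
minimal trap space, so constraints passing all trap spaces pass all stable
states.  An oracle returning no solutions yields **vacuous**, a distinct
status — a context without attractors should alert the modeller, never
silently pass (this also keeps empty expectations from failing).  Under
the propagation oracle a constraint on a free component fails as
"unconstrained".  An optional `select` runs sub-model extraction first,
for local specifications.  Suites are YAML (schema rejects unknown
fields); they can also be rendered as a native pytest module
(`verification.emit_pytest`), the YAML staying canonical.  Cases run
independently — one error never aborts a suite — and totals are invariant
under reordering.

## Synthetic models

The random generator produces expression-tree rules (not random truth
tables), so generated models remain readable in bnet form and round-trip
through the parser.  Parameters: component/input counts, max in-degree
(default 2, the sparse regime typical of curated regulatory rules),
AND-vs-OR bias and literal negation probability (defaults 0.5 / 0.3, mild
mixing so that rules are neither canalising-trivial nor parity-like),
optional multivalued levels with per-level cases filtered for
reachability, and a seed (fully deterministic).  Generated models emulate
the *structure* of curated rule tables — sparse regulation, readable
rules, explicit inputs — but not their biology: no scale-free topology, no
enrichment of feedback loops, no biological naming.  Oracle-agreement
results on them certify algorithmic correctness, not biological adequacy
of any particular model.

Problem sizes used by the shipped checks: stable-state search vs
enumeration on 200 models up to 12 components; trap-space search vs
subspace enumeration on 100 models up to 8; propagation soundness on 100
models up to 10; confluence on 50 models × 10 worklist shuffles.  These
sizes keep the exhaustive oracles exact while the whole suite runs in
seconds.

## Degenerate inputs and numerical choices

Empty clamp sets are valid (constant rules still percolate); clamping a
component twice at different levels is rejected at the CLI; thresholds
and levels are validated against declared bounds everywhere.  The
exhaustive trap-space check refuses subspaces beyond a configurable cap
(default 2^20 states).  For ternary perturbations the CLI clamps at the
maximal level unless a level is given (`--clamp NAME` vs
`--clamp NAME=1`), since a persistently active multivalued receptor is
most naturally modelled at full activity.

## Known limitations

Reachability of attractors and temporal-logic properties are out of
scope.  Trap spaces fix components at single levels; interval subspaces of
multivalued components (e.g. level ∈ {1,2}) are not represented, and
de-Booleanising a trap space of the indicator encoding whose indicators
are only partially fixed raises an error rather than approximating.  The
minimal-trap-space search is for small models; no performance parity with
solver-backed tools is attempted.  GINML/SBML-qual import is not
provided — published models must be converted to a rule table externally.
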