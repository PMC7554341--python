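# logimodel

Tools for building and analysing large **logical models** of cellular
networks — Boolean or multivalued regulatory networks where each component
takes a discrete activity level and is updated by a logic rule over its
regulators.  Large curated models (hundreds of nodes, e.g. signalling
networks assembled from pathway maps) are too big to validate by staring at
simulations; `logimodel` supports a software-engineering style of model
development instead:

* **Value propagation (percolation).**  Clamp components at constant levels
  (persistent inputs, knockouts, ectopic expression), substitute the values
  into downstream rules, simplify, and freeze every rule that becomes
  constant, iterating to quiescence.  The frozen set shows which components
  a context *forces* ON or OFF and which keep degrees of freedom, and two
  contexts (say, activating one co-inhibitory receptor vs another) can be
  compared component-by-component and rendered as a colored regulatory
  graph.
* **Sub-model extraction.**  Pull out a selected component set plus one
  layer of regulators, turning boundary regulators into explorable inputs,
  so fragmentary biological knowledge can be tested locally.
* **Attractor analysis.**  Complete stable-state enumeration (DFS with
  percolation-based pruning) and minimal trap-space computation (hypercubes
  closed under any updating — approximations of complex attractors), with
  brute-force oracles and a threshold-indicator Booleanization for
  multivalued components.
* **Specification-based verification.**  Encode biological expectations as
  YAML test cases — a context of clamps plus expected activities, checked
  against stable states, trap spaces, or propagation — and run them as
  suites with pass / fail / vacuous / error outcomes, like unit tests for
  models.

## The model class

A model is `M = (V, f)`: components `c ∈ V` with levels in
`0..max_level(c)` and one rule `f_c` per component over threshold atoms
(`X:k` ≡ "level of X ≥ k").  Multivalued rules are ordered
`(condition, target_level)` cases with implicit default 0; dynamics move
each component one level per update toward its target.  A component whose
rule is exactly itself (`A, A`) is an *input*.  Rule tables are read and
written in a Boolean `bnet` dialect (`target, factors` lines with `!`, `&`,
`|`) and a native JSON dialect for multivalued models.

## Worked example

The six-node percolation toy: inputs A, B, C, F feed two core nodes with
`D = A | B | C` and `E = D & !F`.  Activating C percolates:

```sh
$ logimodel fixture figure3 --out fig3.bnet
$ logimodel propagate --model fig3.bnet --clamp C=1
component	status	value
A	input	-
B	input	-
C	frozen	1
F	input	-
D	frozen	1
E	free	!F -> 1
# non-input tally: frozen_inactive=0 frozen_active=1 free=1
```

C=1 makes D's rule true regardless of A and B, so D freezes ON; E's rule
simplifies to `!F`, i.e. E becomes entirely dependent on the remaining free
input F.  Comparing two contexts and exporting the annotated graph:

```sh
$ logimodel compare --model fig3.bnet --clamp-a C=1 --clamp-b F=1
impact	A	B	intersection
frozen_inactive	0	1	0
frozen_active	1	0	0
free	1	1	0
```

Row/column layout: frozen-inactive / frozen-active / free counts of
non-input components under context A, context B, and frozen identically in
both.  Here context A (C=1) freezes D ON while E stays free, context B
(F=1) freezes E OFF while D stays free.

Verification of the calcium-handling toys (the ER reservoir `Calcium_ER`
is filled by the SERCA pump and emptied by the IP3R1 channel):

```sh
$ logimodel fixture calcium_default --out ca.bnet
$ logimodel verify --model ca.bnet --suite examples/calcium_suite.yaml
suite calcium-module: pass=1, fail=1, vacuous=0, error=0
  [FAIL   ] rest_reservoir_full_without_pump
            no solution satisfies all constraints; e.g. solution 1: Calcium_ER: expected active, observed level 0
  [PASS   ] channel_open_empties_reservoir
```

The naive rule `Calcium_ER = SERCA & !IP3R1` cannot keep the reservoir
full with the pump off — the suite catches it.  The corrected fixture,
`(SERCA | Calcium_ER) & !IP3R1`, passes both cases: once full, the
reservoir persists while the channel stays closed.

Other subcommands: `validate`, `submodel`, `stable`, `trapspaces`,
`generate` (seeded random models).  Everything is also available as a
library (`import logimodel`).

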