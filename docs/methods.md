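# Methods

## Model class and update semantics

A qualitative network is a finite set of nodes, each with an integer range
[min, max] (at least two levels), connected by signed edges. Node levels
evolve synchronously: at every tick each node evaluates its target function
*T* on the current state and moves one level toward it — up if *T* > level,
down if *T* < level, unchanged on exact equality — then clamps to its range.
The comparison is strict, so a fractional target such as level + 1/2 still
moves the node; this can produce genuine 2-cycles around a fractional
equilibrium, which the midpoint reporting (below) absorbs. Because the state
space is finite and the update deterministic, every trajectory enters a cycle
within |state space| steps: a fixed point (length 1) or a loop. Distinct
attractors reachable from different initial states constitute a bifurcation.

All target arithmetic is exact rational (`fractions.Fraction`). This is not a
nicety: fixed points are decided by exact comparison of a target against an
integer level, and the default function's averages routinely produce values
like 2/3 that a float pipeline would perturb enough to flip a strict
inequality.

## Target functions

The expression grammar covers integer constants, `var(name)` references,
binary `+ − × ÷`, n-ary `avg`/`min`/`max` and unary `ceil`/`floor`. Division
denominators must fold to a non-zero constant — the restriction that keeps
interval evaluation (below) sound and simple. Every referenced variable must
be an in-edge source of the node owning the expression. Before evaluation,
each regulator level is linearly rescaled from the regulator's range into the
regulated node's range; endpoints map to endpoints and the map is monotone.

The default function is avg(pos) − avg(neg). The conventions for empty
regulator sets, which the model class leaves open, are isolated in two
one-line functions (`empty_pos_value` / `empty_neg_value`) so they can be
swapped wholesale:

* no activators but some inhibitors: avg(pos) := the node's max level, so a
  silent inhibitor leaves the node chasing full activation (an
  inhibition-only node behaves as "max minus inhibition");
* no inhibitors: avg(neg) := 0;
* no regulators and no explicit function: the target is the node's current
  level (identity). Unregulated inputs therefore hold whatever a background
  or initial state gives them — which is exactly how genetic backgrounds
  work: they clamp inputs, and everything downstream follows.

## Stable-state bounding

Exhaustive enumeration is exponential, so larger models are analysed by a
greatest-fixpoint interval refinement. One integer interval [lo, hi] per node
starts at the full range; each sweep computes, per node, the extreme target
values attainable over the current box and shrinks the node's interval to its
intersection with [⌊minT⌋, ⌈maxT⌉] clamped to the range. Iteration stops when
nothing changes.

*Soundness.* Every attractor state stays inside the box at every sweep.
Sketch: let v be the largest level node *i* attains across an attractor
contained in the current box. Either the node sits at v permanently — then
(for interior v) its target equals v somewhere in the box, or (at the range
maximum) exceeds it, so ⌈maxT⌉ ≥ v — or the node returns to v after dipping,
in which case some attractor state has T > v − 1, and again ⌈maxT⌉ ≥ v. The
floor/ceil widening is what makes the argument go through under the
strict-inequality step rule. The symmetric argument bounds the minimum.

*Extremal targets.* When a node has ≤ 6 referenced regulators and the box
restricted to them has ≤ 4096 integer points, the extremes are computed
exactly by enumerating regulator combinations. Otherwise the expression AST
is evaluated over intervals: `avg`/`min`/`max` and `+`/`−` are componentwise
monotone, products take the four-corner envelope, divisions are by constants.
Interval evaluation over-approximates when a variable occurs more than once
in an expression; the exact path removes that slack wherever it is cheap.
Decidability is never at stake — only tightness.

*Reporting.* If every interval is a singleton, the single box state is the
network's unique attractor (`proven_unique`), and each node reports its
level. Otherwise nodes report the midpoint (lo + hi)/2 — possibly a
half-integer — and bounded simulation from box corners (all-low and all-high
first, then up to 64 corners ordered by interval width) tries to *exhibit*
at least two attractors. Exhibition is a lower bound: finding one attractor
is reported as "not proven unique", never as "unique".

Termination is immediate: intervals never grow, so at most Σ(range sizes)
sweeps occur. The engine's two correctness claims — containment of every
enumerated attractor state, and enumeration finding exactly one fixed point
whenever uniqueness is proven — are checked property-style against the
brute-force oracle on hundreds of seeded random networks, including
input-clamped variants (clamping is what usually collapses the box, so the
uniqueness path is genuinely exercised).

## Perturbations, backgrounds, screens

Knockout sets a node's target to its minimum, overexpression to its maximum,
`set_level` to a stated level, and a drug expands to one or more node clamps.
Backgrounds are named clamp sets applied before perturbations; a perturbation
targeting a background-clamped node overrides the clamp (needed so a BRAF
inhibitor can act on a mutation-locked kinase) and the override is logged.
Drug effects are modeled as clamps only; capped-but-responsive targets are a
known limitation.

A screen evaluates background × perturbation (and unordered pairs, canonical
label order, self-pairs excluded) with the bounding engine, reports each
behavior readout via the midpoint rule, and stores exact rationals in the
result table (rendering rounds only at presentation). Per-cell failures are
recorded in the row's `error` column without aborting the run. The tumor
growth score of a row is proliferation − apoptosis. Combination ranking
filters pairs whose residency readout exceeds the per-background untreated
baseline in *any* screened background, then sorts by worst-case growth score;
an optional maximum-score cutoff is exposed but off by default, the
filter+rank being the literal selection criterion.

## Validation

Experiment records carry a background, perturbations and measurements in
three dialects — absolute level, closed level range, and direction relative
to the background-only baseline — because literature readouts come at
different precisions. Directional comparisons use strict inequality on
reported (possibly midpoint) levels; exact ties count as "unchanged".
Reported levels come from exact enumeration limits when the state space is
≤ 10⁴ and from interval bounds otherwise; using the tight limits where
feasible means an oracle-labelled experiment set scores exactly 100% rather
than losing measurements to interval slack. Reports are per-measurement
(one experiment may contribute several), so a deviating model run can be
traced to specific records.

## Synthetic generators

The generators define the conditions everything is tested under:

* **Motifs.** `tnf_autocrine` is the bistable switch: ligand → receptor →
  transcription factor → ligand plus a residency node inhibited by the
  ligand. A ring with pure default functions is *not* bistable under
  synchronous updates — every uniform state is a fixed point and token
  rotations form loop attractors — so the ligand's induction is cooperative:
  `floor(min(TF, receptor)/r)·r` with r the max level, requiring both inputs
  at full strength (the discrete analogue of a sigmoidal, cooperative
  response). Enumeration confirms exactly two attractors at r = 1 and r = 2,
  and a max-clamped ligand collapses the count to one. The other motifs
  (mutual activation/inhibition, negative loop, cascades) use defaults.
* **Random networks** draw directed edges independently at a stated density
  with uniform signs, node ranges uniform in 1..max_range, default functions
  throughout, fully reproducible per seed. They are property-test fodder;
  explicit-function coverage comes from motifs and the demo model.
* **Experiment sets** sample a clamping background and 0–2 perturbations per
  record, compute the true reported readout by enumeration, and store it as
  the expectation — 100% validation by construction. A corruption fraction
  shifts round(fraction · n) expectations to provably wrong levels, giving a
  known-failure set for exercising the report.
* **Demo model** (~30 nodes): a synthetic melanoma–LC interaction model, not
  a transcription of any curated one. Driver inputs (BRAF V600E, PTEN,
  CDKN2A, MITF) feed MAPK and PI3K/AKT signaling into proliferation and
  apoptosis; TNF is produced cooperatively from Ets-1, Sp1 and cJUN with
  autocrine reinforcement, MITF represses cJUN (so the MITF-low state locks
  the loop on); the LC side reads TGF-β (pro-residency) against TNF
  (anti-residency) with CSF1/MAPK-dependent survival. Five backgrounds clamp
  every input (healthy plus four BRAF-V600E contexts over PTEN × MITF), and
  a twelve-drug panel clamps pathway nodes. Its design goals are structural:
  a unique low-TNF healthy state, bistability in MITF-high mutants, MITF-low
  lock-in, TGF-β-pathway drugs lowering residency everywhere, MAPK inhibitors
  raising it in MITF-high. What passing tests on synthetic data do *not*
  show: that any curated, literature-derived model validates at a given rate,
  or that real tumors behave as the demo's simplified pathway wiring does.

## Numerical and design choices

* State spaces ≤ 10⁶ may be enumerated (the oracle's cap); validation
  switches from enumeration to interval bounds at 10⁴ states; exact extremal
  evaluation is used up to 6 regulators / 4096 combinations. These sizes keep
  the full test suite and the acceptance script in the tens of seconds on a
  single CPU while leaving the oracle authoritative wherever it runs.
* Cycle detection hashes visited states (full-state key) rather than using
  pointer-chasing tricks — trajectories are short and debuggability wins.
* Pairs in screens are unordered with canonical label ordering; duplicate
  and self-pairs are dropped. Repeated clamps on one node are last-write-wins.
* BMA JSON is the interchange format (numeric `var(id)` references are
  translated to names on read); tabular CSV is the authoring format. Node
  kinds are presentation metadata only and never affect dynamics; the
  `_LC` suffix convention distinguishing LC proteins from their melanoma
  counterparts is preserved verbatim, with no automatic namespacing.
* SBML-qual import/export is out of scope (future work), as are asynchronous
  update schemes, ODE/stochastic semantics, dose–response modeling and any
  spatial structure.

## Known limitations

* Interval bounds can be loose on nodes whose expressions repeat a variable
  and exceed the exact-evaluation budget; the midpoint then blurs toward the
  range center. Soundness is unaffected.
* Exhibiting attractors from box corners is heuristic; a bistable system
  whose second basin contains no sampled corner would be reported (honestly)
  as "not proven unique" without a second witness.
* Drugs are clamps; therapies best modeled as *capping* a target function
  rather than fixing it are not expressible yet.
* The uniqueness proof is all-or-nothing (every interval a singleton); partial
  uniqueness (some nodes fixed, others bistable) is visible in the bounds but
  not certified per node.
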