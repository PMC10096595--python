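# qnsim

An executable **qualitative-network** engine for cell-signaling models, built
for studying how primary melanomas escape immune surveillance by epidermal
Langerhans cells (LCs) — and reusable for any multi-level logical model of the
same family (the format of the BioModelAnalyzer tool).

## The model class

A qualitative network generalizes a Boolean network: each node *X* holds an
integer level in a finite range [a, b] and chases a **target function**
*T(X)* of its regulators' levels. Unless a modeler writes an explicit
expression, the default is

```
T(X) = avg(pos) − avg(neg)
```

over the activators (`pos`) and inhibitors (`neg`) of *X*. A regulator *X*
with range a–b feeding a node *X′* with range a′–b′ is first rescaled as
(X − a)(b′ − a′)/(b − a) + a′. All nodes update **synchronously**, each moving
one level per tick toward its target (clamped to its range), so from any
initial state the system deterministically reaches an attractor: a
**fixed point** (one state) or a **loop** (a state cycle). Multiple attractors
from different initial states form a **bifurcation** — the discrete face of
bistability, here created by the autocrine TNF-α positive-feedback loop of
melanoma cells: loop *off* (small tumors, LCs stay resident) vs. loop *on*
(large or dedifferentiated MITF-low tumors, TNF-α expels LCs).

On top of the dynamics, the package provides:

* **exhaustive attractor enumeration** — the brute-force oracle for state
  spaces up to ~10⁶;
* **stable-state bounding** for large models: a sound greatest-fixpoint
  interval refinement that either proves a unique fixed point or reports
  per-node limits, with loop/bifurcation levels summarized as the midpoint
  (lo + hi)/2;
* **in silico screening** — knockouts (target := minimum), overexpression
  (target := maximum), drugs (bundles of node clamps) and genetic backgrounds,
  singly and in pairwise combination, with the **tumor growth score** =
  proliferation − apoptosis, and ranking of combinations that never raise LC
  residency above the untreated baseline;
* **validation** of a model against experiment tables (absolute-level, level
  range, or directional expectations) with per-measurement verdicts;
* **model I/O**: BMA-compatible JSON and a tabular CSV authoring format;
* **synthetic generators**: named motifs (including the bistable autocrine
  switch), seeded random networks, oracle-labelled experiment sets, and a
  ~30-node synthetic melanoma–LC demo model with five genetic backgrounds and
  a twelve-drug panel.

## Worked example

```python
from qnsim import enumerate_attractors, bound_stable_states, exhibit_attractors, synthetic

net = synthetic.make_motif("tnf_autocrine", max_level=2)
print(len(enumerate_attractors(net)))          # 2
bounds = bound_stable_states(net)
print(bounds.proven_unique)                    # False
print(len(exhibit_attractors(net, bounds)))    # 2
```

The motif — ligand → receptor → transcription factor → ligand, with
cooperative ligand induction and a residency node inhibited by the ligand —
has exactly two attractors: all-low with `Residency_LC = 2` and all-high with
`Residency_LC = 0`. The interval engine keeps every interval at [0, 2]
(reported midpoint 1), correctly refusing to claim a unique stable state, and
corner simulation exhibits both steady states. Clamping the ligand at 2
collapses the system to one attractor: the loop locked on.

The screening pipeline on the demo model (`examples/03_drug_screen.py`)
prints baseline LC residency per background —

```
healthy: 2
BRAF_MITFhigh: 3/2
BRAF_PTENloss_MITFhigh: 3/2
BRAF_MITFlow: 1
BRAF_PTENloss_MITFlow: 1
```

— the half-integer values marking the bistable MITF-high backgrounds (the
model sits in either the loop-off or loop-on state, so the midpoint of the
limits is reported). Exactly three drugs, all acting on TGF-β signaling
(`TGFB1_mAb`, `SIS3`, `GW788388`), lower residency in every background, and
the combination ranking in the `BRAF_PTENloss_MITFhigh` background surfaces
pairs like MDM2 + E2F inhibition with growth score −1/2, while excluding every
pair that would trap LCs in the epidermis.

Each script in `examples/` is a short, runnable tour of one capability.
A thin CLI mirrors the library: `qnsim simulate|stable|screen|validate|generate|convert`.

## Running the curated models

The fully curated LC (38 nodes / 46 edges), melanoma (89 nodes / 162 edges)
and combined melanoma–LC models, with their background, therapy and
literature-experiment tables, are not bundled. Users who transcribe them can
drop the CSVs under `data/models/{lc,melanoma,combined}/` (schemas in
`qnsim.model_io`) and the table-driven tests in `tests/test_acceptance.py`
plus the CLI will run them unchanged.

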