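"""Prove bistability two ways: brute force and interval bounds.

Exhaustive enumeration (feasible here: 81 states) finds the motif's two
attractors exactly.  The interval-refinement engine — the tool that scales to
models far beyond enumeration — cannot collapse the box, correctly refuses to
claim uniqueness, and corner simulation exhibits both steady states.
Clamping the ligand at its maximum (the analogue of a dedifferentiated,
constitutively secreting tumor state) collapses the system to one attractor.
"""

from qnsim import (
    bound_stable_states,
    enumerate_attractors,
    exhibit_attractors,
    summarize_level,
    synthetic,
)

net = synthetic.make_motif("tnf_autocrine", max_level=2)

attractors = enumerate_attractors(net)
print(f"enumeration: {len(attractors)} attractors")
for a in attractors:
    print(f"  fixed point: {a.states[0]}")

bounds = bound_stable_states(net)
print(f"\ninterval bounds (proven_unique={bounds.proven_unique}):")
for node, (lo, hi) in bounds.bounds.items():
    print(f"  {node}: [{lo}, {hi}]  reported level {summarize_level(bounds, node)}")

exhibited = exhibit_attractors(net, bounds)
print(f"\ncorner simulation exhibits {len(exhibited)} steady states "
      f"(TNF levels {sorted(a.states[0]['TNF'] for a in exhibited)})")

locked = net.with_targets({"TNF": 2})
print(f"ligand clamped at max: {len(enumerate_attractors(locked))} attractor "
      "(the loop is forced on)")

# Reported levels for non-unique analyses are interval midpoints — e.g. TNF
# reports 1 here, meaning 'either 0 or 2 depending on the loop's history'.
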