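"""Stable-state bounding for large networks.

Exhaustive attractor enumeration is exponential in the node count, so models
beyond desk scale are analysed by *interval refinement*: keep one integer
interval [lo, hi] per node, start from the full ranges, and repeatedly shrink
each interval to its intersection with the clamped, integer-widened range of
target values attainable over the current box.  The refinement is a greatest
fixpoint:

* soundness — every state of every attractor stays inside the box at every
  sweep (one-step-toward-target dynamics cannot hold a node at a level the
  widened target interval excludes);
* monotonicity — intervals never grow, so the loop terminates after at most
  the sum of all range sizes sweeps;
* best-effort tightness — when every interval shrinks to a single level the
  unique remaining box state is a proven-unique fixed point; otherwise the
  analysis reports bounds only, and reports per-node levels as the midpoint
  (lo + hi) / 2, matching how loop/bifurcation outcomes are summarised.

Extremal targets are computed by exhaustive evaluation over all regulator
level combinations when that is cheap (exact), and by interval evaluation of
the expression AST otherwise (sound over-approximation: avg/min/max and +/-
are componentwise monotone, and products/divisions are interval-safe).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import islice, product

from .dynamics import Attractor, compile_stepper, simulate
from .network import QualitativeNetwork, scale_regulator

__all__ = [
    "NodeBounds",
    "bound_stable_states",
    "summarize_level",
    "exhibit_attractors",
]

# exact extremal-target evaluation is used when a node has at most this many
# regulators and at most this many level combinations over the current box
EXACT_MAX_REGULATORS = 6
EXACT_MAX_COMBINATIONS = 4096


@dataclass(frozen=True)
class NodeBounds:
    """Per-node intervals [lo, hi] containing every attractor state, plus a
    uniqueness flag (True only when all intervals are singletons, in which
    case the single box state is the network's only attractor)."""

    bounds: dict[str, tuple[int, int]]
    proven_unique: bool

    def __getitem__(self, node: str) -> tuple[int, int]:
        return self.bounds[node]

    def __contains__(self, node: str) -> bool:
        return node in self.bounds

    def contains_state(self, state) -> bool:
        return all(lo <= state[n] <= hi for n, (lo, hi) in self.bounds.items())

    @property
    def is_singleton(self) -> bool:
        return all(lo == hi for lo, hi in self.bounds.values())

    def singleton_state(self) -> dict[str, int]:
        if not self.is_singleton:
            raise ValueError("bounds are not a single state")
        return {n: lo for n, (lo, hi) in self.bounds.items()}


def _extremal_target(
    network: QualitativeNetwork, name: str, box: dict[str, tuple[int, int]]
) -> tuple[Fraction, Fraction]:
    """(min, max) of the node's target over the current box."""
    node = network.nodes[name]
    expr = network.compiled_target(name)
    variables = sorted(expr.variables())

    n_comb = 1
    for var in variables:
        lo, hi = box[var]
        n_comb *= hi - lo + 1
    if len(variables) <= EXACT_MAX_REGULATORS and n_comb <= EXACT_MAX_COMBINATIONS:
        # exact: enumerate every regulator-level combination
        lo_t = hi_t = None
        ranges = [range(box[v][0], box[v][1] + 1) for v in variables]
        for combo in product(*ranges):
            env = {
                v: scale_regulator(lvl, network.nodes[v].range, node.range)
                for v, lvl in zip(variables, combo)
            }
            t = expr.evaluate(env)
            if lo_t is None or t < lo_t:
                lo_t = t
            if hi_t is None or t > hi_t:
                hi_t = t
        assert lo_t is not None and hi_t is not None
        return lo_t, hi_t

    env_iv = {}
    for v in variables:
        lo, hi = box[v]
        env_iv[v] = (
            scale_regulator(lo, network.nodes[v].range, node.range),
            scale_regulator(hi, network.nodes[v].range, node.range),
        )
    return expr.interval(env_iv)


def bound_stable_states(network: QualitativeNetwork) -> NodeBounds:
    """Greatest-fixpoint interval refinement of the network's stable states.

    Returns sound bounds: every state of every attractor (fixed point or
    loop) lies inside the returned box.  ``proven_unique`` is True iff the box
    shrank to a single state, which is then the unique attractor.
    """
    box = {name: network.nodes[name].range for name in network.node_order}
    changed = True
    while changed:
        changed = False
        for name in network.node_order:
            node = network.nodes[name]
            lo, hi = box[name]
            min_t, max_t = _extremal_target(network, name, box)
            # floor/ceil widening keeps half-integer targets sound under the
            # strict-inequality step rule
            cand_lo = max(node.min_level, min(node.max_level, math.floor(min_t)))
            cand_hi = max(node.min_level, min(node.max_level, math.ceil(max_t)))
            new_lo = max(lo, cand_lo)
            new_hi = min(hi, cand_hi)
            if new_lo > new_hi:  # pragma: no cover - would indicate a bug
                raise RuntimeError(
                    f"refinement emptied the interval of node {name!r}; "
                    "soundness invariant violated"
                )
            if (new_lo, new_hi) != (lo, hi):
                box[name] = (new_lo, new_hi)
                changed = True
    return NodeBounds(bounds=box, proven_unique=all(lo == hi for lo, hi in box.values()))


def summarize_level(analysis, node: str) -> Fraction:
    """The reported level of ``node``.

    A proven-unique fixed point (or a single enumerated fixed-point attractor)
    reports the level itself; a loop or bifurcation reports the midpoint
    (lo + hi) / 2 of the limits, which may be a half-integer.

    ``analysis`` is either a :class:`NodeBounds` or a list of
    :class:`~qnsim.dynamics.Attractor` from the enumeration oracle.
    """
    if isinstance(analysis, NodeBounds):
        if node not in analysis:
            raise KeyError(f"unknown node {node!r}")
        lo, hi = analysis[node]
    else:
        attractors = list(analysis)
        if not attractors:
            raise ValueError("no attractors to summarize")
        levels = [lvl for a in attractors for lvl in a.levels(node)]
        lo, hi = min(levels), max(levels)
    if lo == hi:
        return Fraction(lo)
    return Fraction(lo + hi, 2)


def _box_corners(bounds: NodeBounds, order, limit: int):
    """Corners of the box, widest-interval dimensions varied first, all-lo and
    all-hi corners guaranteed."""
    free = [n for n in order if bounds[n][0] < bounds[n][1]]
    free.sort(key=lambda n: bounds[n][1] - bounds[n][0], reverse=True)
    base_lo = {n: bounds[n][0] for n in order}
    base_hi = {n: bounds[n][1] for n in order}
    yield base_lo
    yield base_hi
    seen = 2
    for combo in islice(product((0, 1), repeat=len(free)), 2 ** min(len(free), 20)):
        if seen >= limit:
            return
        corner = dict(base_lo)
        for n, bit in zip(free, combo):
            corner[n] = bounds[n][bit]
        if corner != base_lo and corner != base_hi:
            yield corner
            seen += 1


def exhibit_attractors(
    network: QualitativeNetwork,
    bounds: NodeBounds | None = None,
    max_corners: int = 64,
    max_steps: int = 10_000,
) -> list[Attractor]:
    """Bounded simulation from box corners, to exhibit distinct attractors
    when the bounds did not prove uniqueness (e.g. the two steady states of a
    bistable positive-feedback loop).

    Returns the distinct attractors actually reached — a *lower* bound on the
    attractor count.  Finding only one does not prove uniqueness; callers must
    report that case as "not proven unique", never as "unique".
    """
    if bounds is None:
        bounds = bound_stable_states(network)
    stepper = compile_stepper(network)
    found: dict[tuple, Attractor] = {}
    for corner in _box_corners(bounds, network.node_order, max_corners):
        res = simulate(network, corner, max_steps=max_steps, _stepper=stepper)
        if res.attractor is None:
            continue
        key = tuple(tuple(sorted(s.items())) for s in res.attractor.states)
        found.setdefault(key, res.attractor)
    return list(found.values())
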