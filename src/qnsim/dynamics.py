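"""Synchronous update semantics and exhaustive attractor enumeration.

Every node moves at most one level per tick, toward its target: with current
level v and target value T (an exact rational),

    next = v + 1  if T > v
    next = v - 1  if T < v
    next = v      otherwise,

then clamped to the node's range.  The comparison is strict, so a fractional
target such as v + 1/2 still moves the node (the stability module's midpoint
reporting absorbs the resulting 2-cycles).  The update is a deterministic
function of the full state; from any initial state the trajectory enters a
cycle within |state space| steps.  A cycle of length 1 is a fixed point;
longer cycles are loops; more than one attractor is a bifurcation.

``enumerate_attractors`` is the brute-force oracle used throughout the test
suite: it simulates from *every* initial state and therefore only applies to
small state spaces (default cap 10^6).  Large models go through
:mod:`qnsim.stability` instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Callable, Iterator

from .network import NetworkError, QualitativeNetwork, check_state, scale_regulator

__all__ = [
    "Attractor",
    "SimulationResult",
    "step",
    "simulate",
    "enumerate_attractors",
    "compile_stepper",
    "is_fixed_point",
]

StateTuple = tuple[int, ...]


@dataclass(frozen=True)
class Attractor:
    """A fixed point (one state) or loop (several, in visit order), plus one
    initial state known to reach it."""

    states: tuple[dict[str, int], ...]
    basin_witness: dict[str, int]

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def __len__(self) -> int:
        return len(self.states)

    def levels(self, node: str) -> tuple[int, ...]:
        return tuple(s[node] for s in self.states)


@dataclass(frozen=True)
class SimulationResult:
    trajectory: tuple[dict[str, int], ...]
    attractor: Attractor | None  # None iff the step budget ran out

    @property
    def converged(self) -> bool:
        return self.attractor is not None


def compile_stepper(network: QualitativeNetwork) -> Callable[[StateTuple], StateTuple]:
    """Build a fast synchronous-step function over tuple states (levels in
    ``network.node_order``).  Regulator scaling is folded into per-edge affine
    coefficients; all arithmetic stays exact."""
    order = network.node_order
    index = {name: i for i, name in enumerate(order)}
    evaluators = []
    for name in order:
        node = network.nodes[name]
        expr = network.compiled_target(name)
        coeffs = {}
        for var in expr.variables():
            src = network.nodes.get(var)
            if src is None:
                raise NetworkError(f"var({var}) in target of {name!r} names no node")
            # scaled = lvl * m + c, with endpoints mapping to endpoints
            m = Fraction(node.max_level - node.min_level, src.max_level - src.min_level)
            c = Fraction(node.min_level) - Fraction(src.min_level) * m
            coeffs[var] = (index[var], m, c)
        evaluators.append((index[name], node.min_level, node.max_level, expr, coeffs))

    def step_tuple(state: StateTuple) -> StateTuple:
        nxt = list(state)
        for i, lo, hi, expr, coeffs in evaluators:
            env = {var: state[j] * m + c for var, (j, m, c) in coeffs.items()}
            target = expr.evaluate(env)
            v = state[i]
            if target > v:
                v += 1
            elif target < v:
                v -= 1
            if v < lo:
                v = lo
            elif v > hi:
                v = hi
            nxt[i] = v
        return tuple(nxt)

    return step_tuple


def _to_tuple(network: QualitativeNetwork, state) -> StateTuple:
    return tuple(state[name] for name in network.node_order)


def _to_dict(network: QualitativeNetwork, state: StateTuple) -> dict[str, int]:
    return dict(zip(network.node_order, state))


def step(network: QualitativeNetwork, state) -> dict[str, int]:
    """One synchronous update of every node simultaneously."""
    check_state(network, state)
    stepper = compile_stepper(network)
    return _to_dict(network, stepper(_to_tuple(network, state)))


def is_fixed_point(network: QualitativeNetwork, state) -> bool:
    """Directly check the fixed-point condition, without simulating: for every
    node the target must compare equal-or-toward-clamp."""
    stepper = compile_stepper(network)
    t = _to_tuple(network, state)
    return stepper(t) == t


def _canonical_cycle(cycle: tuple[StateTuple, ...]) -> tuple[StateTuple, ...]:
    """Rotate a cycle so equal cycles entered at different states compare equal."""
    k = cycle.index(min(cycle))
    return cycle[k:] + cycle[:k]


def simulate(
    network: QualitativeNetwork,
    init,
    max_steps: int = 10_000,
    _stepper: Callable[[StateTuple], StateTuple] | None = None,
) -> SimulationResult:
    """Iterate the synchronous update from ``init`` until a state repeats.

    The trajectory records every distinct state visited (starting with
    ``init``); the attractor is the cycle closed by the first revisit.  If
    ``max_steps`` updates pass without a revisit (only possible when the
    budget is smaller than the number of states visited) the result carries
    ``attractor=None``.
    """
    check_state(network, init)
    stepper = _stepper or compile_stepper(network)
    current = _to_tuple(network, init)
    seen: dict[StateTuple, int] = {current: 0}
    path = [current]
    for _ in range(max_steps):
        current = stepper(current)
        if current in seen:
            cycle = _canonical_cycle(tuple(path[seen[current] :]))
            return SimulationResult(
                trajectory=tuple(_to_dict(network, s) for s in path),
                attractor=Attractor(
                    states=tuple(_to_dict(network, s) for s in cycle),
                    basin_witness=_to_dict(network, path[0]),
                ),
            )
        seen[current] = len(path)
        path.append(current)
    return SimulationResult(
        trajectory=tuple(_to_dict(network, s) for s in path), attractor=None
    )


def _all_states(network: QualitativeNetwork) -> Iterator[StateTuple]:
    ranges = [
        range(network.nodes[name].min_level, network.nodes[name].max_level + 1)
        for name in network.node_order
    ]
    return product(*ranges)


def enumerate_attractors(
    network: QualitativeNetwork, state_space_cap: int = 10**6
) -> list[Attractor]:
    """All attractors, by simulating from every initial state (the oracle).

    Refuses state spaces above ``state_space_cap`` — use
    :func:`qnsim.stability.bound_stable_states` for large networks.  More than
    one returned attractor is a bifurcation.
    """
    size = network.state_space_size()
    if size > state_space_cap:
        raise NetworkError(
            f"state space has {size} states, above the cap of {state_space_cap}; "
            "use qnsim.stability.bound_stable_states for large networks"
        )
    stepper = compile_stepper(network)
    successor: dict[StateTuple, StateTuple] = {}

    def succ(s: StateTuple) -> StateTuple:
        nxt = successor.get(s)
        if nxt is None:
            nxt = successor[s] = stepper(s)
        return nxt

    # color: attractor index each state drains to (assigned once per state)
    color: dict[StateTuple, int] = {}
    attractors: list[Attractor] = []
    cycle_keys: dict[tuple[StateTuple, ...], int] = {}
    for start in _all_states(network):
        if start in color:
            continue
        path = [start]
        positions = {start: 0}
        current = start
        while True:
            current = succ(current)
            if current in color:
                idx = color[current]
                break
            if current in positions:
                cycle = _canonical_cycle(tuple(path[positions[current] :]))
                idx = cycle_keys.get(cycle)
                if idx is None:
                    idx = len(attractors)
                    cycle_keys[cycle] = idx
                    attractors.append(
                        Attractor(
                            states=tuple(_to_dict(network, s) for s in cycle),
                            basin_witness=_to_dict(network, start),
                        )
                    )
                break
            positions[current] = len(path)
            path.append(current)
        for s in path:
            color[s] = idx
    return attractors
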