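"""Qualitative-network data model.

A qualitative network generalizes a Boolean network: each node holds an
integer *level* in a finite range [min_level, max_level] and, under the
synchronous update scheme (see :mod:`qnsim.dynamics`), moves one step per tick
toward the value of its target function.  Signed edges classify each regulator
as an activator (``pos``) or inhibitor (``neg``); the default target function
is avg(pos) - avg(neg), with regulator levels linearly rescaled into the
regulated node's range first.

Conventions for the default function when a regulator set is empty (isolated
in :func:`empty_pos_value` / :func:`empty_neg_value` so they can be swapped):

* empty ``pos`` with non-empty ``neg``  ->  avg(pos) := the node's max_level,
  so inhibition opposes full activation;
* empty ``neg``                          ->  avg(neg) := 0;
* no regulators at all and no explicit function -> the target is the node's
  current level (identity), so an unclamped input node holds whatever a
  background or initial state gives it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

from .expressions import (
    Call,
    Const,
    Expr,
    ExpressionError,
    UnresolvedReference,
    Var,
    check_references,
    parse_expression,
)

__all__ = [
    "NodeDef",
    "EdgeDef",
    "QualitativeNetwork",
    "NetworkState",
    "NetworkError",
    "scale_regulator",
    "evaluate_target",
    "parse_target_expression",
    "validate_network",
]

#: A network state maps every node name to an integer level.
NetworkState = Mapping[str, int]

ACTIVATING = "activating"
INHIBITING = "inhibiting"

NODE_KINDS = (
    "protein",
    "complex",
    "gene",
    "receptor",
    "secreted",
    "process",
    "drug-action",
)


class NetworkError(ValueError):
    """Structural problem with a network definition."""


@dataclass(frozen=True)
class NodeDef:
    """One network node: a protein, gene, receptor, secreted factor, drug
    action, or an observable cell process such as proliferation.

    ``target`` is either an expression string (see :mod:`qnsim.expressions`),
    ``"default"``/None for avg(pos) - avg(neg), or a pre-built
    :class:`~qnsim.expressions.Expr`.  ``kind`` is metadata only (it drives
    presentation, never dynamics).
    """

    name: str
    min_level: int = 0
    max_level: int = 2
    target: str | Expr | None = None
    kind: str = "protein"

    @property
    def range(self) -> tuple[int, int]:
        return (self.min_level, self.max_level)

    @property
    def n_levels(self) -> int:
        return self.max_level - self.min_level + 1


@dataclass(frozen=True)
class EdgeDef:
    """A signed regulatory edge; ``sign`` decides whether ``source`` joins the
    pos (activators) or neg (inhibitors) set of ``target``'s default function."""

    source: str
    target: str
    sign: str = ACTIVATING

    def __post_init__(self):
        if self.sign not in (ACTIVATING, INHIBITING):
            raise NetworkError(
                f"edge {self.source}->{self.target}: sign must be "
                f"{ACTIVATING!r} or {INHIBITING!r}, got {self.sign!r}"
            )


def empty_pos_value(node: NodeDef) -> Expr:
    """avg(pos) convention when a node has inhibitors but no activators."""
    return Const(Fraction(node.max_level))


def empty_neg_value(node: NodeDef) -> Expr:
    """avg(neg) convention when a node has no inhibitors."""
    return Const(Fraction(0))


def scale_regulator(
    level: int | Fraction,
    source_range: tuple[int, int],
    target_range: tuple[int, int],
) -> Fraction:
    """Rescale a regulator level from its own range (a, b) into the regulated
    node's range (a', b') via (level - a) * (b' - a') / (b - a) + a'.

    Exact rational arithmetic; endpoints map to endpoints and the map is
    monotone increasing.
    """
    a, b = source_range
    a2, b2 = target_range
    if not (a < b and a2 < b2):
        raise NetworkError(f"degenerate range in scaling: {source_range} -> {target_range}")
    if not (a <= level <= b):
        raise NetworkError(f"level {level} outside source range {source_range}")
    return (Fraction(level) - a) * (b2 - a2) / (b - a) + a2


class QualitativeNetwork:
    """An executable multi-level logical network.

    Construction is permissive (so :func:`validate_network` can report every
    problem at once); operations that execute the network compile the target
    functions on first use and raise on an invalid definition.
    """

    def __init__(
        self,
        nodes: Iterable[NodeDef],
        edges: Iterable[EdgeDef] = (),
        behavior_nodes: Iterable[str] = (),
        name: str = "",
    ):
        self.nodes: dict[str, NodeDef] = {}
        for n in nodes:
            if n.name in self.nodes:
                raise NetworkError(f"duplicate node name {n.name!r}")
            self.nodes[n.name] = n
        self.edges: tuple[EdgeDef, ...] = tuple(edges)
        self.behavior_nodes: tuple[str, ...] = tuple(behavior_nodes)
        self.name = name
        self.node_order: tuple[str, ...] = tuple(self.nodes)
        self._compiled: dict[str, Expr] = {}

    # -- structure ----------------------------------------------------------

    def regulators(self, node: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """(activators, inhibitors) of ``node``, in edge order."""
        pos = tuple(e.source for e in self.edges if e.target == node and e.sign == ACTIVATING)
        neg = tuple(e.source for e in self.edges if e.target == node and e.sign == INHIBITING)
        return pos, neg

    def in_sources(self, node: str) -> tuple[str, ...]:
        pos, neg = self.regulators(node)
        return pos + neg

    def state_space_size(self) -> int:
        size = 1
        for n in self.nodes.values():
            size *= n.n_levels
        return size

    # -- target compilation -------------------------------------------------

    def compiled_target(self, node: str) -> Expr:
        """The node's target function as an AST, with "default" expanded."""
        if node not in self._compiled:
            self._compiled[node] = parse_target_expression(
                self.nodes[node].target, self.nodes[node], self
            )
        return self._compiled[node]

    # -- derived copies -----------------------------------------------------

    def with_targets(self, overrides: Mapping[str, str | Expr | int]) -> "QualitativeNetwork":
        """A copy with some nodes' target functions replaced.  Integer values
        become constant targets (clamps).  The original is untouched."""
        new_nodes = []
        for n in self.nodes.values():
            if n.name in overrides:
                ov = overrides[n.name]
                if isinstance(ov, int):
                    if not (n.min_level <= ov <= n.max_level):
                        raise NetworkError(
                            f"clamp level {ov} outside range of node {n.name!r}"
                        )
                    ov = Const(Fraction(ov))
                new_nodes.append(replace(n, target=ov))
            else:
                new_nodes.append(n)
        unknown = set(overrides) - set(self.nodes)
        if unknown:
            raise NetworkError(f"override(s) for unknown node(s) {sorted(unknown)}")
        return QualitativeNetwork(new_nodes, self.edges, self.behavior_nodes, self.name)

    def __repr__(self):  # pragma: no cover
        return (
            f"QualitativeNetwork({self.name or 'unnamed'}: "
            f"{len(self.nodes)} nodes, {len(self.edges)} edges)"
        )


def parse_target_expression(
    text: str | Expr | None, node: NodeDef, network: QualitativeNetwork
) -> Expr:
    """Parse a node's target-function text into an AST.

    None or ``"default"`` expand to avg(pos) - avg(neg) under the module's
    empty-set conventions; a regulator-free default becomes the identity
    (a self-reference, holding the current level).  Every var reference must
    name an in-edge source of ``node``.
    """
    pos, neg = network.regulators(node.name)
    if text is None or (isinstance(text, str) and text.strip().lower() == "default"):
        if not pos and not neg:
            return Var(node.name)  # identity: unregulated input node
        pos_part = Call("avg", tuple(Var(s) for s in pos)) if pos else empty_pos_value(node)
        neg_part = Call("avg", tuple(Var(s) for s in neg)) if neg else empty_neg_value(node)
        return BinOpSub(pos_part, neg_part)
    if isinstance(text, Expr):
        expr = text
    else:
        expr = parse_expression(
            text,
            pos_args=tuple(Var(s) for s in pos),
            neg_args=tuple(Var(s) for s in neg),
            empty_pos=empty_pos_value(node),
            empty_neg=empty_neg_value(node),
        )
    allowed = set(pos) | set(neg) | {node.name}
    check_references(expr, sorted(allowed), owner=node.name)
    return expr


def BinOpSub(a: Expr, b: Expr) -> Expr:
    from .expressions import BinOp

    # avg(pos) - 0 is kept as written only when there are inhibitors; the
    # trailing "- 0" is dropped for readability of unparsed defaults
    if isinstance(b, Const) and b.value == 0:
        return a
    return BinOp("-", a, b)


def evaluate_target(
    node: NodeDef | str, state: NetworkState, network: QualitativeNetwork
) -> Fraction:
    """Evaluate a node's target function in ``state``.

    Every var(X) is first rescaled from X's range into the node's own range
    (identity when the ranges coincide); the result is an exact rational and
    may lie outside [min_level, max_level] — clamping belongs to the dynamics.
    """
    if isinstance(node, str):
        node = network.nodes[node]
    expr = network.compiled_target(node.name)
    env: dict[str, Fraction] = {}
    for name in expr.variables():
        src = network.nodes.get(name)
        if src is None:
            raise UnresolvedReference(f"var({name}) names no node in the network")
        env[name] = scale_regulator(state[name], src.range, node.range)
    return expr.evaluate(env)


def validate_network(network: QualitativeNetwork) -> list[str]:
    """Structural diagnostics; an empty list means every invariant holds.

    Checks: degenerate ranges, dangling edges, unresolvable or out-of-grammar
    target functions, behavior nodes that are not nodes.
    """
    diags: list[str] = []
    for n in network.nodes.values():
        if n.min_level >= n.max_level:
            diags.append(
                f"degenerate-range: node {n.name!r} has min {n.min_level} >= max {n.max_level}"
            )
    for e in network.edges:
        for endpoint in (e.source, e.target):
            if endpoint not in network.nodes:
                diags.append(
                    f"dangling-edge: {e.source}->{e.target} references missing node {endpoint!r}"
                )
    for b in network.behavior_nodes:
        if b not in network.nodes:
            diags.append(f"unknown-behavior-node: {b!r}")
    for n in network.nodes.values():
        if any(d.startswith("dangling-edge") and f"->{n.name} " in d for d in diags):
            continue
        try:
            network.compiled_target(n.name)
        except ExpressionError as exc:
            diags.append(f"bad-target: node {n.name!r}: {exc}")
    return diags


def check_state(network: QualitativeNetwork, state: NetworkState) -> None:
    """Raise NetworkError unless ``state`` assigns every node an in-range level."""
    missing = set(network.nodes) - set(state)
    if missing:
        raise NetworkError(f"state missing node(s) {sorted(missing)}")
    for name, node in network.nodes.items():
        lvl = state[name]
        if not (node.min_level <= lvl <= node.max_level):
            raise NetworkError(
                f"level {lvl} of node {name!r} outside range {node.range}"
            )
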