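"""Mutations, drugs, backgrounds, and in silico screens.

A *perturbation* replaces one or more target functions by constants:

* ``knockout``    — constant at the node's minimum (inactivation);
* ``overexpress`` — constant at the node's maximum (activation);
* ``set_level``   — constant at a stated level;
* ``drug``        — a named bundle of node clamps from a :class:`DrugDef`.

A *background* is a named set of clamps representing a genetic/transcriptional
context (e.g. BRAF V600E with MITF high, or healthy skin); backgrounds are
applied before perturbations, and a perturbation targeting a background-
clamped node overrides the clamp (so a drug can act on a mutant-locked node —
this is logged).  Screens run the stability analysis for every background x
perturbation (and unordered pair) and report each behavior readout as the
summarized stable level; the tumor growth score of a row is
proliferation - apoptosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .network import NetworkError, QualitativeNetwork
from .stability import bound_stable_states, summarize_level

__all__ = [
    "Perturbation",
    "DrugDef",
    "Background",
    "ScreenResult",
    "apply_perturbation",
    "apply_background",
    "run_screen",
    "tumor_growth_score",
    "select_optimal_combinations",
]

logger = logging.getLogger(__name__)

KINDS = ("knockout", "overexpress", "set_level", "drug")


@dataclass(frozen=True)
class DrugDef:
    """A targeted therapy, modeled as clamps on its target node(s).

    ``overrides`` maps node name -> clamp level (a kinase inhibitor clamps its
    target at minimum; an agonist at maximum).  ``source`` is free-text
    provenance (e.g. the authoring table row).
    """

    name: str
    overrides: tuple[tuple[str, int], ...]
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "overrides", tuple((n, int(l)) for n, l in self.overrides))


@dataclass(frozen=True)
class Perturbation:
    kind: str
    node: str = ""
    level: int | None = None
    drug: DrugDef | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise NetworkError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "set_level" and self.level is None:
            raise NetworkError("set_level perturbation needs a level")
        if self.kind == "drug" and self.drug is None:
            raise NetworkError("drug perturbation needs a DrugDef")

    @staticmethod
    def knockout(node: str) -> "Perturbation":
        return Perturbation("knockout", node)

    @staticmethod
    def overexpress(node: str) -> "Perturbation":
        return Perturbation("overexpress", node)

    @staticmethod
    def set_level(node: str, level: int) -> "Perturbation":
        return Perturbation("set_level", node, level=level)

    @staticmethod
    def of_drug(drug: DrugDef) -> "Perturbation":
        return Perturbation("drug", drug.name, drug=drug)

    def clamps(self, network: QualitativeNetwork) -> dict[str, int]:
        """The node -> level clamps this perturbation expands to."""
        if self.kind == "drug":
            assert self.drug is not None
            return dict(self.drug.overrides)
        if self.node not in network.nodes:
            raise NetworkError(f"perturbation targets unknown node {self.node!r}")
        node = network.nodes[self.node]
        if self.kind == "knockout":
            return {self.node: node.min_level}
        if self.kind == "overexpress":
            return {self.node: node.max_level}
        assert self.level is not None
        if not (node.min_level <= self.level <= node.max_level):
            raise NetworkError(
                f"set_level {self.level} outside range {node.range} of {self.node!r}"
            )
        return {self.node: self.level}

    @property
    def label(self) -> str:
        if self.kind == "drug":
            return f"drug:{self.node}"
        if self.kind == "set_level":
            return f"set:{self.node}={self.level}"
        prefix = "ko" if self.kind == "knockout" else "oe"
        return f"{prefix}:{self.node}"


@dataclass(frozen=True)
class Background:
    """A named genetic/transcriptional context, applied as clamps before any
    perturbation."""

    name: str
    clamps: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "clamps", tuple((n, int(l)) for n, l in self.clamps))


def apply_background(network: QualitativeNetwork, background: Background) -> QualitativeNetwork:
    return network.with_targets(dict(background.clamps))


def apply_perturbation(network: QualitativeNetwork, p: Perturbation) -> QualitativeNetwork:
    """A modified copy of the network with the perturbation's clamps applied;
    the original network is untouched.  Later clamps on the same node are
    last-write-wins."""
    return network.with_targets(p.clamps(network))


def _perturbed(
    network: QualitativeNetwork,
    background: Background | None,
    perturbations: Sequence[Perturbation],
) -> QualitativeNetwork:
    clamps: dict[str, int] = {}
    if background is not None:
        clamps.update(background.clamps)
    for p in perturbations:
        for node, level in p.clamps(network).items():
            if background is not None and node in dict(background.clamps):
                logger.info(
                    "perturbation %s overrides background %s clamp on node %s",
                    p.label, background.name, node,
                )
            clamps[node] = level
    return network.with_targets(clamps)


GROWTH_COL = "tumor_growth_score"


@dataclass
class ScreenResult:
    """A screen's result table: one row per (background, perturbation[, pair]),
    readout columns holding exact rationals (rendering rounds only at
    presentation), plus the tumor growth score when both proliferation and
    apoptosis were read out."""

    table: pd.DataFrame
    readouts: tuple[str, ...]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        for col in list(self.readouts) + ([GROWTH_COL] if GROWTH_COL in out else []):
            out[col] = out[col].map(
                lambda v: "" if v is None else format(float(v), ".6g")
            )
        out.to_csv(path, index=False)

    def to_json(self) -> list[dict]:
        records = []
        for _, row in self.table.iterrows():
            rec = {}
            for k, v in row.items():
                rec[k] = float(v) if isinstance(v, Fraction) else v
            records.append(rec)
        return records

    def row(self, background: str, p1: str = "", p2: str = "") -> pd.Series:
        t = self.table
        hit = t[
            (t["background"] == background)
            & (t["perturbation_1"] == p1)
            & (t["perturbation_2"] == p2)
        ]
        if hit.empty:
            raise KeyError(f"no screen row for ({background!r}, {p1!r}, {p2!r})")
        return hit.iloc[0]


def tumor_growth_score(row, proliferation: str = "Proliferation", apoptosis: str = "Apoptosis") -> Fraction:
    """proliferation - apoptosis for one result row (mapping or Series)."""
    try:
        p, a = row[proliferation], row[apoptosis]
    except KeyError as exc:
        raise NetworkError(f"growth score needs readout {exc} in the row") from exc
    if p is None or a is None:
        raise NetworkError("growth score undefined for a failed cell")
    return Fraction(p) - Fraction(a)


def run_screen(
    network: QualitativeNetwork,
    backgrounds: Sequence[Background],
    perturbations: Sequence[Perturbation] = (),
    readouts: Sequence[str] | None = None,
    pairwise: bool = False,
    proliferation: str = "Proliferation",
    apoptosis: str = "Apoptosis",
) -> ScreenResult:
    """Run the in silico screen.

    For every background the screen reports a baseline row (no perturbation),
    one row per perturbation and, when ``pairwise``, one row per unordered
    pair of distinct perturbations (self-pairs excluded; pairs are canonically
    ordered by label so duplicates collapse).  Each cell applies background
    clamps, then the perturbation clamps, bounds the stable states and
    summarizes each readout.  A failure in one cell is recorded in that row's
    ``error`` column and the screen continues.
    """
    if not backgrounds:
        raise NetworkError("screen needs at least one background")
    if readouts is None:
        readouts = network.behavior_nodes
    readouts = tuple(readouts)
    unknown = set(readouts) - set(network.nodes)
    if unknown:
        raise NetworkError(f"readout(s) {sorted(unknown)} are not network nodes")
    with_growth = proliferation in readouts and apoptosis in readouts

    jobs: list[tuple[Background, tuple[Perturbation, ...]]] = []
    for bg in backgrounds:
        jobs.append((bg, ()))
        for p in perturbations:
            jobs.append((bg, (p,)))
        if pairwise:
            ordered = sorted(perturbations, key=lambda p: p.label)
            for p1, p2 in combinations(ordered, 2):
                jobs.append((bg, (p1, p2)))

    rows = []
    for bg, ps in jobs:
        row: dict = {
            "background": bg.name,
            "perturbation_1": ps[0].label if len(ps) > 0 else "",
            "perturbation_2": ps[1].label if len(ps) > 1 else "",
        }
        try:
            modified = _perturbed(network, bg, ps)
            bounds = bound_stable_states(modified)
            for r in readouts:
                row[r] = summarize_level(bounds, r)
            if with_growth:
                row[GROWTH_COL] = tumor_growth_score(row, proliferation, apoptosis)
            row["error"] = ""
        except Exception as exc:  # cell failure: record and continue
            for r in readouts:
                row.setdefault(r, None)
            if with_growth:
                row.setdefault(GROWTH_COL, None)
            row["error"] = str(exc)
        rows.append(row)

    cols = ["background", "perturbation_1", "perturbation_2", *readouts]
    if with_growth:
        cols.append(GROWTH_COL)
    cols.append("error")
    return ScreenResult(table=pd.DataFrame(rows, columns=cols), readouts=readouts)


def select_optimal_combinations(
    result: ScreenResult,
    residency_node: str,
    baseline: ScreenResult | None = None,
    max_growth_score: Fraction | None = None,
) -> pd.DataFrame:
    """Rank admissible drug pairs of a pairwise screen.

    A pair is *admissible* when, in every background of the screen, its
    residency readout does not exceed the background's baseline residency
    (so the treatment never traps antigen-presenting cells in the tissue).
    Admissible pairs are ranked by their worst (highest) tumor growth score
    across backgrounds, lowest first.  ``max_growth_score``, when given,
    additionally drops pairs whose ranked score exceeds it.
    """
    if residency_node not in result.readouts:
        raise NetworkError(f"residency node {residency_node!r} was not a screen readout")
    base = baseline if baseline is not None else result
    t = result.table
    pair_rows = t[(t["perturbation_1"] != "") & (t["perturbation_2"] != "")]
    baseline_rows = base.table[
        (base.table["perturbation_1"] == "") & (base.table["perturbation_2"] == "")
    ]
    base_res = {r["background"]: r[residency_node] for _, r in baseline_rows.iterrows()}

    ranked = []
    for (p1, p2), grp in pair_rows.groupby(["perturbation_1", "perturbation_2"]):
        admissible = True
        worst_score = None
        for _, row in grp.iterrows():
            bg = row["background"]
            if row["error"] or row[residency_node] is None or bg not in base_res:
                admissible = False
                break
            if row[residency_node] > base_res[bg]:
                admissible = False
                break
            if GROWTH_COL in row and row[GROWTH_COL] is not None:
                s = row[GROWTH_COL]
                if worst_score is None or s > worst_score:
                    worst_score = s
        if not admissible:
            continue
        if max_growth_score is not None and worst_score is not None and worst_score > max_growth_score:
            continue
        ranked.append({"perturbation_1": p1, "perturbation_2": p2, "score": worst_score})
    out = pd.DataFrame(ranked, columns=["perturbation_1", "perturbation_2", "score"])
    return out.sort_values(
        by=["score", "perturbation_1", "perturbation_2"], kind="mergesort"
    ).reset_index(drop=True)
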