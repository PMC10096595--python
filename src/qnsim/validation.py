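"""Scoring encoded models against experiment tables.

Each experiment record names a genetic background, a list of perturbations
(gene knockouts/overexpressions, level settings, drugs) and one or more
measurements: a readout node together with an expected outcome.  Because
literature readouts come at different precisions, three expectation dialects
are supported:

* ``level``     — the reported stable level equals a stated value;
* ``range``     — the reported level falls in a closed interval [lo, hi];
* ``direction`` — ``increase`` / ``decrease`` / ``unchanged`` relative to the
  unperturbed background baseline, compared with strict inequality on the
  (possibly half-integer midpoint) reported levels; an exact tie counts as
  ``unchanged``.

Reported levels come from the same stable-state analysis used everywhere
else: a proven-unique fixed point reports its level, a loop or bifurcation
reports the midpoint of the per-node limits.  For state spaces small enough
to enumerate, the limits are the exact min/max over all attractor states;
larger networks fall back to the interval bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from .dynamics import enumerate_attractors
from .network import NetworkError, QualitativeNetwork
from .perturbation import Background, Perturbation, _perturbed
from .stability import bound_stable_states, summarize_level

__all__ = [
    "Measurement",
    "ExperimentRecord",
    "MeasurementVerdict",
    "ValidationReport",
    "run_experiment",
    "score_experiments",
]

EXPECTATION_KINDS = ("level", "range", "direction")
DIRECTIONS = ("increase", "decrease", "unchanged")

#: state spaces up to this size are analysed by exact enumeration
ENUMERATION_CAP = 10_000


@dataclass(frozen=True)
class Measurement:
    readout: str
    kind: str  # level | range | direction
    value: object  # int | (lo, hi) | direction string

    def __post_init__(self):
        if self.kind not in EXPECTATION_KINDS:
            raise NetworkError(f"unknown expectation kind {self.kind!r}")
        if self.kind == "direction" and self.value not in DIRECTIONS:
            raise NetworkError(f"unknown direction {self.value!r}")

    def passes(self, predicted: Fraction, baseline: Fraction | None) -> bool:
        if self.kind == "level":
            return predicted == Fraction(self.value)  # type: ignore[arg-type]
        if self.kind == "range":
            lo, hi = self.value  # type: ignore[misc]
            return Fraction(lo) <= predicted <= Fraction(hi)
        if baseline is None:
            raise NetworkError("directional expectation needs a baseline level")
        if self.value == "increase":
            return predicted > baseline
        if self.value == "decrease":
            return predicted < baseline
        return predicted == baseline


@dataclass(frozen=True)
class ExperimentRecord:
    id: str
    background: Background
    perturbations: tuple[Perturbation, ...] = ()
    measurements: tuple[Measurement, ...] = ()

    def __post_init__(self):
        if not self.measurements:
            raise NetworkError(f"experiment {self.id!r} has no measurements")


@dataclass(frozen=True)
class MeasurementVerdict:
    experiment_id: str
    readout: str
    expectation: str
    predicted: Fraction
    baseline: Fraction | None
    passed: bool


@dataclass
class ValidationReport:
    verdicts: list[MeasurementVerdict] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.verdicts)

    @property
    def n_pass(self) -> int:
        return sum(v.passed for v in self.verdicts)

    @property
    def percent(self) -> float:
        return 100.0 * self.n_pass / self.n_total

    def failures(self) -> list[MeasurementVerdict]:
        return [v for v in self.verdicts if not v.passed]

    def to_json(self) -> dict:
        return {
            "n_pass": self.n_pass,
            "n_total": self.n_total,
            "percent": self.percent,
            "verdicts": [
                {
                    "experiment": v.experiment_id,
                    "readout": v.readout,
                    "expectation": v.expectation,
                    "predicted": float(v.predicted),
                    "baseline": None if v.baseline is None else float(v.baseline),
                    "passed": v.passed,
                }
                for v in self.verdicts
            ],
        }

    def to_text(self) -> str:
        lines = [f"{self.n_pass}/{self.n_total} measurements passed ({self.percent:.1f}%)"]
        for v in self.verdicts:
            mark = "PASS" if v.passed else "FAIL"
            base = "" if v.baseline is None else f" (baseline {v.baseline})"
            lines.append(
                f"  [{mark}] {v.experiment_id}: {v.readout} expected {v.expectation}, "
                f"predicted {v.predicted}{base}"
            )
        return "\n".join(lines)


def _reported_levels(
    network: QualitativeNetwork, nodes: Sequence[str], enumeration_cap: int
) -> dict[str, Fraction]:
    if network.state_space_size() <= enumeration_cap:
        analysis: object = enumerate_attractors(network, state_space_cap=enumeration_cap)
    else:
        analysis = bound_stable_states(network)
    return {n: summarize_level(analysis, n) for n in nodes}


def run_experiment(
    network: QualitativeNetwork,
    record: ExperimentRecord,
    enumeration_cap: int = ENUMERATION_CAP,
) -> tuple[dict[str, Fraction], dict[str, Fraction]]:
    """Reproduce the experiment's conditions in the model.

    Returns ``(predicted, baseline)``: the reported level of every measured
    readout under background + perturbations, and under the background alone
    (needed for directional expectations).
    """
    for m in record.measurements:
        if m.readout not in network.nodes:
            raise NetworkError(
                f"experiment {record.id!r} reads out unknown node {m.readout!r}"
            )
    readouts = [m.readout for m in record.measurements]
    try:
        perturbed = _perturbed(network, record.background, record.perturbations)
        base_net = _perturbed(network, record.background, ())
    except NetworkError as exc:
        raise NetworkError(f"experiment {record.id!r}: {exc}") from exc
    predicted = _reported_levels(perturbed, readouts, enumeration_cap)
    baseline = _reported_levels(base_net, readouts, enumeration_cap)
    return predicted, baseline


def score_experiments(
    network: QualitativeNetwork,
    records: Sequence[ExperimentRecord],
    enumeration_cap: int = ENUMERATION_CAP,
) -> ValidationReport:
    """Measurement-level validation of the model against a record list.

    One experiment may contribute several measurements; the report counts
    each measurement separately.  Deterministic and independent of record
    order.
    """
    if not records:
        raise NetworkError("cannot score an empty experiment list")
    report = ValidationReport()
    for record in records:
        predicted, baseline = run_experiment(network, record, enumeration_cap)
        for m in record.measurements:
            if m.kind == "level":
                expectation = f"level {m.value}"
            elif m.kind == "range":
                expectation = f"level in [{m.value[0]}, {m.value[1]}]"
            else:
                expectation = str(m.value)
            base = baseline[m.readout] if m.kind == "direction" else None
            report.verdicts.append(
                MeasurementVerdict(
                    experiment_id=record.id,
                    readout=m.readout,
                    expectation=expectation,
                    predicted=predicted[m.readout],
                    baseline=base,
                    passed=m.passes(predicted[m.readout], baseline[m.readout]),
                )
            )
    return report
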