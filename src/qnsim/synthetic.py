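"""Synthetic networks and experiment sets.

Everything the analysis pipeline consumes can be generated here, so every
stage is testable without external model tables:

* small named motifs with known attractor structure, including an autocrine
  positive-feedback loop (``tnf_autocrine``) engineered to be bistable;
* seeded random networks with default target functions, as property-test
  fodder for the enumeration-oracle-vs-interval-bounds containment check;
* experiment record sets whose expected outcomes are computed by the
  exhaustive enumeration oracle — an uncorrupted set must validate at exactly
  100%, and a corrupted set must fail at exactly the corrupted measurements;
* a ~30-node synthetic melanoma–Langerhans-cell interaction model
  (:func:`demo_model`) with five genetic backgrounds and a targeted-drug
  panel, exercising the full screening pipeline.

Design note on ``tnf_autocrine``: a plain three-node ring with default
(average) functions is *not* bistable under the synchronous semantics — every
uniform state is a fixed point and token-rotation loops appear — so the
ligand's induction is made cooperative and switch-like:
``floor(min(TF, receptor) / r) * r`` (r = the common max level), which needs
both receptor engagement and transcription-factor activity at full strength.
Brute-force enumeration then shows exactly two attractors (loop off / loop
on) at r = 1 and r = 2, and clamping the ligand at maximum collapses the
system to a single attractor — the analogue of a dedifferentiated state
locking the loop on.
"""

from __future__ import annotations

import math
from typing import Sequence

import networkx as nx
import numpy as np

from .dynamics import enumerate_attractors
from .network import (
    ACTIVATING,
    INHIBITING,
    EdgeDef,
    NetworkError,
    NodeDef,
    QualitativeNetwork,
)
from .perturbation import Background, DrugDef, Perturbation, _perturbed
from .stability import summarize_level
from .validation import ExperimentRecord, Measurement

__all__ = [
    "MOTIFS",
    "make_motif",
    "generate_random_network",
    "generate_experiment_set",
    "demo_model",
    "demo_backgrounds",
    "demo_drugs",
]

MOTIFS = (
    "tnf_autocrine",
    "mutual_activation",
    "mutual_inhibition",
    "negative_loop",
    "linear_cascade",
)


def make_motif(name: str, max_level: int = 2, cascade_length: int = 3) -> QualitativeNetwork:
    """Build a named motif; all nodes share the range [0, max_level].

    ``tnf_autocrine``: ligand -> receptor -> transcription factor -> ligand
    (a directed positive cycle) with cooperative ligand induction (see the
    module docstring), plus a residency proxy node inhibited by the ligand.
    Exactly two attractors: all-low (loop off, residency high) and all-high
    (loop on, residency at minimum).

    ``linear_cascade``: In -> M1 -> ... -> Out with default functions; with
    the input clamped, the unique stable state propagates the clamp.
    """
    r = max_level
    if r < 1:
        raise NetworkError("max_level must be >= 1")
    if name == "tnf_autocrine":
        nodes = [
            NodeDef("TNF", 0, r, f"floor(min(var(TF), var(TNFR)) / {r}) * {r}", kind="secreted"),
            NodeDef("TNFR", 0, r, kind="receptor"),
            NodeDef("TF", 0, r, kind="protein"),
            NodeDef("Residency_LC", 0, r, kind="process"),
        ]
        edges = [
            EdgeDef("TNF", "TNFR"),
            EdgeDef("TNFR", "TF"),
            EdgeDef("TF", "TNF"),
            EdgeDef("TNFR", "TNF"),  # cooperative reinforcement of induction
            EdgeDef("TNF", "Residency_LC", INHIBITING),
        ]
        return QualitativeNetwork(nodes, edges, behavior_nodes=("Residency_LC",), name=name)
    if name == "mutual_activation":
        nodes = [NodeDef("A", 0, r), NodeDef("B", 0, r)]
        edges = [EdgeDef("A", "B"), EdgeDef("B", "A")]
        return QualitativeNetwork(nodes, edges, name=name)
    if name == "mutual_inhibition":
        nodes = [NodeDef("A", 0, r), NodeDef("B", 0, r)]
        edges = [EdgeDef("A", "B", INHIBITING), EdgeDef("B", "A", INHIBITING)]
        return QualitativeNetwork(nodes, edges, name=name)
    if name == "negative_loop":
        nodes = [NodeDef("A", 0, r), NodeDef("B", 0, r)]
        edges = [EdgeDef("A", "B"), EdgeDef("B", "A", INHIBITING)]
        return QualitativeNetwork(nodes, edges, name=name)
    if name == "linear_cascade":
        if cascade_length < 2:
            raise NetworkError("cascade needs at least 2 nodes")
        names = ["In"] + [f"M{i}" for i in range(1, cascade_length - 1)] + ["Out"]
        nodes = [NodeDef(n, 0, r) for n in names]
        edges = [EdgeDef(a, b) for a, b in zip(names, names[1:])]
        return QualitativeNetwork(nodes, edges, name=name)
    raise NetworkError(f"unknown motif {name!r}; choose one of {MOTIFS}")


def generate_random_network(
    n_nodes: int,
    edge_density: float,
    max_range: int = 2,
    seed: int = 0,
) -> QualitativeNetwork:
    """A seeded random network with default target functions.

    Directed edges are drawn independently with probability ``edge_density``
    (self-loops excluded), each uniformly activating or inhibiting; node max
    levels are drawn uniformly from 1..max_range.  ``max_range=1`` gives the
    Boolean special case.  Identical seeds give identical networks.
    """
    if n_nodes < 1 or not (0 < edge_density <= 1) or max_range < 1:
        raise NetworkError("need n_nodes >= 1, 0 < edge_density <= 1, max_range >= 1")
    rng = np.random.default_rng(seed)
    graph = nx.gnp_random_graph(
        n_nodes, edge_density, directed=True, seed=int(rng.integers(2**31))
    )
    names = [f"N{i}" for i in range(n_nodes)]
    nodes = [
        NodeDef(names[i], 0, int(rng.integers(1, max_range + 1))) for i in range(n_nodes)
    ]
    edges = [
        EdgeDef(names[u], names[v], ACTIVATING if rng.random() < 0.5 else INHIBITING)
        for u, v in sorted(graph.edges())
    ]
    return QualitativeNetwork(nodes, edges, name=f"random(n={n_nodes}, seed={seed})")


def generate_experiment_set(
    network: QualitativeNetwork,
    n_records: int,
    seed: int = 0,
    corrupt_fraction: float = 0.0,
    enumeration_cap: int = 10_000,
) -> tuple[list[ExperimentRecord], list[str]]:
    """Sample experiment records whose expectations are oracle-computed.

    Each record applies a random background (clamping a random subset of
    nodes) plus zero or more knockout/overexpression perturbations, computes
    the true reported level of a random readout via exhaustive attractor
    enumeration, and stores it as the expectation — so an uncorrupted set
    validates at exactly 100% by construction.  ``corrupt_fraction`` shifts
    the expectation of round(fraction * n_records) records to a provably
    wrong level.  Returns ``(records, corrupted_ids)``.
    """
    if network.state_space_size() > enumeration_cap:
        raise NetworkError("network too large for the enumeration oracle")
    rng = np.random.default_rng(seed)
    names = list(network.node_order)
    records: list[ExperimentRecord] = []
    n_corrupt = int(round(corrupt_fraction * n_records))
    corrupted_ids: list[str] = []
    for i in range(n_records):
        k = int(rng.integers(1, max(1, len(names) // 2) + 1))
        bg_nodes = list(rng.choice(names, size=k, replace=False))
        clamps = tuple(
            (n, int(rng.integers(network.nodes[n].min_level, network.nodes[n].max_level + 1)))
            for n in bg_nodes
        )
        background = Background(name=f"bg{i}", clamps=clamps)
        free = [n for n in names if n not in bg_nodes]
        n_pert = int(rng.integers(0, 3)) if free else 0
        pert_nodes = list(rng.choice(free, size=min(n_pert, len(free)), replace=False))
        perturbations = tuple(
            Perturbation.knockout(n) if rng.random() < 0.5 else Perturbation.overexpress(n)
            for n in pert_nodes
        )
        readout = str(rng.choice(names))
        modified = _perturbed(network, background, perturbations)
        attractors = enumerate_attractors(modified, state_space_cap=enumeration_cap)
        truth = summarize_level(attractors, readout)
        corrupt = i < n_corrupt
        if corrupt:
            node = network.nodes[readout]
            # shift to a level provably different from the truth
            wrong = truth + 1 if truth + 1 <= node.max_level else truth - 1
            expectation = Measurement(readout, "level", wrong)
            corrupted_ids.append(f"syn{i}")
        elif truth.denominator == 1:
            expectation = Measurement(readout, "level", int(truth))
        else:
            # midpoint truth: use the containing half-unit range
            expectation = Measurement(
                readout, "range", (math.floor(truth), math.ceil(truth))
            )
        records.append(
            ExperimentRecord(
                id=f"syn{i}",
                background=background,
                perturbations=perturbations,
                measurements=(expectation,),
            )
        )
    return records, corrupted_ids


# ---------------------------------------------------------------------------
# Synthetic melanoma-LC demo model
# ---------------------------------------------------------------------------


def demo_model() -> QualitativeNetwork:
    """A synthetic ~30-node melanoma–LC interaction model (a stand-in for a
    fully curated model, not a transcription of one).

    The melanoma half links driver inputs (BRAF V600E, PTEN, CDKN2A, MITF) to
    proliferation and apoptosis through MAPK and PI3K/AKT signaling, and
    produces TNF cooperatively from Ets-1, Sp1 and cJUN with autocrine
    reinforcement via its receptor, so that in MITF-high mutant backgrounds
    the TNF loop is bistable while the MITF-low state (which derepresses
    cJUN) locks it on.  The LC half reads TGF-beta (residency-promoting) and
    melanoma TNF (residency-opposing) into the Residency_LC behavior node,
    with CSF1/MAPK-dependent survival and proliferation.
    """
    nodes = [
        # --- inputs clamped by backgrounds ---
        NodeDef("BRAF_V600E", 0, 1, kind="gene"),
        NodeDef("PTEN", 0, 2, kind="gene"),
        NodeDef("CDKN2A", 0, 1, kind="gene"),
        NodeDef("MITF", 0, 2, kind="gene"),
        NodeDef("TGFB", 0, 2, kind="secreted"),
        NodeDef("CSF1", 0, 2, kind="secreted"),
        # --- melanoma MAPK cascade ---
        NodeDef("BRAF", 0, 2),
        NodeDef("MEK", 0, 2),
        NodeDef("ERK", 0, 2),
        NodeDef("Ets1", 0, 2),
        NodeDef("Sp1", 0, 2, target="2"),  # constitutive
        NodeDef("cJUN", 0, 2, target="max(2 - var(MITF), var(TNFR_m))"),
        # --- autocrine TNF loop ---
        NodeDef("TNF", 0, 2, target="floor(min(var(Ets1), var(Sp1), var(cJUN)) / 2) * 2",
                kind="secreted"),
        NodeDef("TNFR_m", 0, 2, kind="receptor"),
        NodeDef("NFkB", 0, 2),
        # --- PI3K/AKT and cell-cycle/apoptosis machinery ---
        NodeDef("PI3K", 0, 2),
        NodeDef("AKT", 0, 2),
        NodeDef("MDM2", 0, 2, target="max(var(AKT), 1)"),
        NodeDef("p53", 0, 2),
        NodeDef("CyclinD_CDK4", 0, 2),
        NodeDef("E2F", 0, 2),
        NodeDef("Proliferation", 0, 2, kind="process"),
        NodeDef("Apoptosis", 0, 2, kind="process"),
        # --- Langerhans cell ---
        NodeDef("TBR_LC", 0, 2, kind="receptor"),
        NodeDef("TNFR_LC", 0, 2, kind="receptor"),
        NodeDef("CSF1R_LC", 0, 2, kind="receptor"),
        NodeDef("ERK_LC", 0, 2),
        NodeDef("Residency_LC", 0, 2,
                target="max(var(TBR_LC) - var(TNFR_LC), floor(var(TBR_LC) / 2))",
                kind="process"),
        NodeDef("Survival_LC", 0, 2, target="ceil(avg(pos))", kind="process"),
        NodeDef("Proliferation_LC", 0, 2, kind="process"),
    ]
    A, I = ACTIVATING, INHIBITING
    edges = [
        EdgeDef("BRAF_V600E", "BRAF", A),
        EdgeDef("BRAF", "MEK", A),
        EdgeDef("MEK", "ERK", A),
        EdgeDef("ERK", "Ets1", A),
        EdgeDef("MITF", "cJUN", I),
        EdgeDef("TNFR_m", "cJUN", A),
        EdgeDef("Ets1", "TNF", A),
        EdgeDef("Sp1", "TNF", A),
        EdgeDef("cJUN", "TNF", A),
        EdgeDef("TNF", "TNFR_m", A),
        EdgeDef("TNFR_m", "NFkB", A),
        EdgeDef("PTEN", "PI3K", I),
        EdgeDef("PI3K", "AKT", A),
        EdgeDef("AKT", "MDM2", A),
        EdgeDef("MDM2", "p53", I),
        EdgeDef("ERK", "CyclinD_CDK4", A),
        EdgeDef("AKT", "CyclinD_CDK4", A),
        EdgeDef("CDKN2A", "CyclinD_CDK4", I),
        EdgeDef("CyclinD_CDK4", "E2F", A),
        EdgeDef("E2F", "Proliferation", A),
        EdgeDef("p53", "Apoptosis", A),
        EdgeDef("NFkB", "Apoptosis", I),
        EdgeDef("AKT", "Apoptosis", I),
        EdgeDef("TGFB", "TBR_LC", A),
        EdgeDef("TNF", "TNFR_LC", A),
        EdgeDef("CSF1", "CSF1R_LC", A),
        EdgeDef("CSF1R_LC", "ERK_LC", A),
        EdgeDef("TBR_LC", "Residency_LC", A),
        EdgeDef("TNFR_LC", "Residency_LC", I),
        EdgeDef("ERK_LC", "Survival_LC", A),
        EdgeDef("TBR_LC", "Survival_LC", A),
        EdgeDef("ERK_LC", "Proliferation_LC", A),
    ]
    return QualitativeNetwork(
        nodes,
        edges,
        behavior_nodes=(
            "Proliferation",
            "Apoptosis",
            "Residency_LC",
            "Survival_LC",
            "Proliferation_LC",
        ),
        name="demo-melanoma-lc",
    )


def demo_backgrounds() -> list[Background]:
    """Four mutant backgrounds plus a healthy-skin control.

    Every input node is clamped in every background so the stable state is
    fully determined by genotype plus the autocrine loop's own state.
    """
    common = (("TGFB", 2), ("CSF1", 1))
    mutant = (("BRAF_V600E", 1), ("CDKN2A", 0))
    return [
        Background("healthy", (("BRAF_V600E", 0), ("PTEN", 2), ("CDKN2A", 1), ("MITF", 1)) + common),
        Background("BRAF_MITFhigh", mutant + (("PTEN", 2), ("MITF", 2)) + common),
        Background("BRAF_PTENloss_MITFhigh", mutant + (("PTEN", 0), ("MITF", 2)) + common),
        Background("BRAF_MITFlow", mutant + (("PTEN", 2), ("MITF", 0)) + common),
        Background("BRAF_PTENloss_MITFlow", mutant + (("PTEN", 0), ("MITF", 0)) + common),
    ]


def demo_drugs() -> list[DrugDef]:
    """A targeted-therapy panel for the demo model, one clamp set per drug.

    Kinase inhibitors clamp their target at minimum; the MEK and ERK
    inhibitors also hit the LC MAPK pathway.  The BRAF inhibitor is modeled
    identically whether it is named dabrafenib or vemurafenib, so a single
    entry carries both names.
    """
    return [
        DrugDef("dabrafenib", (("BRAF", 0),), source="mutant BRAF inhibitor (alias vemurafenib)"),
        DrugDef("trametinib", (("MEK", 0), ("ERK_LC", 0)), source="MEK inhibitor"),
        DrugDef("ulixertinib", (("ERK", 0), ("ERK_LC", 0)), source="ERK inhibitor"),
        DrugDef("TGFB1_mAb", (("TGFB", 0),), source="TGF-beta1 monoclonal antibody"),
        DrugDef("SIS3", (("TBR_LC", 0),), source="SMAD3/TGF-beta signaling inhibitor"),
        DrugDef("GW788388", (("TBR_LC", 0), ("TGFB", 0)), source="TGF-beta receptor inhibitor"),
        DrugDef("copanlisib", (("PI3K", 0),), source="PI3K inhibitor"),
        DrugDef("capivasertib", (("AKT", 0),), source="AKT inhibitor"),
        DrugDef("BMS-345541", (("NFkB", 0),), source="IKK inhibitor"),
        DrugDef("idasanutlin", (("MDM2", 0),), source="MDM2 inhibitor"),
        DrugDef("abemaciclib", (("CyclinD_CDK4", 0),), source="CDK4 inhibitor"),
        DrugDef("HLM006474", (("E2F", 0),), source="E2F inhibitor"),
    ]
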