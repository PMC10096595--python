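"""Reading and writing models, drug/background tables, and experiment tables.

Two model formats are supported:

* **BMA JSON** — the interchange format of the BioModelAnalyzer tool
  (``Model.Variables`` with Id/Name/RangeFrom/RangeTo/Formula and
  ``Model.Relationships`` with FromVariable/ToVariable/Type
  Activator|Inhibitor).  An empty Formula means the default target function.
  ``Layout`` blocks are preserved opaquely on round-trip but never
  interpreted.  Node kinds and behavior-node lists ride along in non-BMA
  extension keys (``Kind``, ``BehaviorNodes``) that the web tool ignores.

* **Tabular CSV** — the authoring format: ``nodes.csv`` (name,min,max,kind),
  ``edges.csv`` (source,target,sign) and ``functions.csv`` (node,expression);
  nodes absent from the functions table get the default function.

Screen inputs are CSV as well: ``drugs.csv`` (drug,node,level[,source]),
``backgrounds.csv`` (background,node,level) and ``experiments.csv``
(id,background,perturbations,readout,expectation_kind,expectation_value),
where ``perturbations`` is a ';'-separated list of tokens
``ko:NODE | oe:NODE | set:NODE=LEVEL | drug:NAME``.  Readers reject rather
than coerce malformed values, naming the offending row or JSON path.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .network import (
    ACTIVATING,
    INHIBITING,
    EdgeDef,
    NetworkError,
    NodeDef,
    QualitativeNetwork,
)
from .perturbation import Background, DrugDef, Perturbation
from .validation import ExperimentRecord, Measurement

__all__ = [
    "FormatError",
    "ModelDocument",
    "read_bma_json",
    "write_bma_json",
    "read_model_tables",
    "write_model_tables",
    "read_screen_tables",
    "write_experiments_csv",
]


class FormatError(ValueError):
    """Malformed document or table."""


@dataclass
class ModelDocument:
    """A model plus its serialization context (format tag, opaque layout,
    provenance notes); read o write o read is stable."""

    network: QualitativeNetwork
    format: str = "bma-json"  # or "tabular"
    layout: dict | None = None
    provenance: dict = field(default_factory=dict)


_SIGN_ALIASES = {
    "activating": ACTIVATING,
    "activator": ACTIVATING,
    "+": ACTIVATING,
    "inhibiting": INHIBITING,
    "inhibitor": INHIBITING,
    "-": INHIBITING,
}


def _canon_sign(raw: str, where: str) -> str:
    sign = _SIGN_ALIASES.get(str(raw).strip().lower())
    if sign is None:
        raise FormatError(f"{where}: unknown edge sign {raw!r}")
    return sign


# ---------------------------------------------------------------------------
# BMA JSON
# ---------------------------------------------------------------------------


def read_bma_document(source) -> ModelDocument:
    """Read a BMA model JSON file, path, or already-parsed dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = source
    model = doc.get("Model")
    if model is None:
        raise FormatError("missing key: $.Model")
    variables = model.get("Variables")
    if variables is None:
        raise FormatError("missing key: $.Model.Variables")
    relationships = model.get("Relationships", [])

    id_to_name: dict[int, str] = {}
    nodes = []
    for i, var in enumerate(variables):
        path = f"$.Model.Variables[{i}]"
        for key in ("Id", "Name", "RangeFrom", "RangeTo"):
            if key not in var:
                raise FormatError(f"missing key: {path}.{key}")
        id_to_name[int(var["Id"])] = str(var["Name"])
        nodes.append((var, path))

    def translate_formula(text: str) -> str:
        # BMA formulas may reference regulators as var(<numeric id>)
        def repl(m: re.Match) -> str:
            vid = int(m.group(1))
            if vid not in id_to_name:
                raise FormatError(f"formula references unknown variable id {vid}")
            return f"var({id_to_name[vid]})"

        return re.sub(r"var\(\s*(\d+)\s*\)", repl, text)

    node_defs = []
    for var, path in nodes:
        formula = str(var.get("Formula") or "").strip()
        node_defs.append(
            NodeDef(
                name=str(var["Name"]),
                min_level=int(var["RangeFrom"]),
                max_level=int(var["RangeTo"]),
                target=translate_formula(formula) if formula else None,
                kind=str(var.get("Kind", "protein")),
            )
        )

    edges = []
    for i, rel in enumerate(relationships):
        path = f"$.Model.Relationships[{i}]"
        for key in ("FromVariable", "ToVariable", "Type"):
            if key not in rel:
                raise FormatError(f"missing key: {path}.{key}")
        rtype = str(rel["Type"])
        if rtype not in ("Activator", "Inhibitor"):
            raise FormatError(f"{path}.Type: unknown relationship type {rtype!r}")
        for endpoint in ("FromVariable", "ToVariable"):
            if int(rel[endpoint]) not in id_to_name:
                raise FormatError(f"{path}.{endpoint}: unknown variable id {rel[endpoint]}")
        edges.append(
            EdgeDef(
                source=id_to_name[int(rel["FromVariable"])],
                target=id_to_name[int(rel["ToVariable"])],
                sign=ACTIVATING if rtype == "Activator" else INHIBITING,
            )
        )

    network = QualitativeNetwork(
        node_defs,
        edges,
        behavior_nodes=tuple(doc.get("BehaviorNodes", ())),
        name=str(model.get("Name", "")),
    )
    from .network import validate_network

    diags = validate_network(network)
    if diags:
        raise FormatError("invalid model: " + "; ".join(diags))
    return ModelDocument(network=network, format="bma-json", layout=doc.get("Layout"))


def read_bma_json(source) -> QualitativeNetwork:
    """Read a BMA model JSON document into a validated network."""
    return read_bma_document(source).network


def write_bma_json(network: QualitativeNetwork, path=None, layout: dict | None = None) -> dict:
    """Serialize to BMA model JSON (canonical key order, ids assigned in node
    order).  Returns the document; also writes it to ``path`` if given."""
    name_to_id = {name: i + 1 for i, name in enumerate(network.node_order)}
    variables = []
    for name in network.node_order:
        node = network.nodes[name]
        target = node.target
        if target is None or (isinstance(target, str) and target.strip().lower() == "default"):
            formula = ""
        elif isinstance(target, str):
            formula = target
        else:
            formula = target.unparse()
        variables.append(
            {
                "Id": name_to_id[name],
                "Name": name,
                "RangeFrom": node.min_level,
                "RangeTo": node.max_level,
                "Formula": formula,
                "Kind": node.kind,
            }
        )
    relationships = [
        {
            "Id": len(network.nodes) + i + 1,
            "FromVariable": name_to_id[e.source],
            "ToVariable": name_to_id[e.target],
            "Type": "Activator" if e.sign == ACTIVATING else "Inhibitor",
        }
        for i, e in enumerate(network.edges)
    ]
    doc: dict = {
        "Model": {
            "Name": network.name,
            "Variables": variables,
            "Relationships": relationships,
        },
        "BehaviorNodes": list(network.behavior_nodes),
    }
    if layout is not None:
        doc["Layout"] = layout
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=False)
            fh.write("\n")
    return doc


# ---------------------------------------------------------------------------
# Tabular model format
# ---------------------------------------------------------------------------


def _read_csv(path, required: Sequence[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}")
    return df


def _int_cell(value, what: str) -> int:
    try:
        return int(str(value).strip())
    except ValueError:
        raise FormatError(f"{what}: {value!r} is not an integer") from None


def read_model_tables(nodes_csv, edges_csv, functions_csv=None,
                      behavior_nodes: Sequence[str] = (), name: str = "") -> QualitativeNetwork:
    """Assemble a validated network from the tabular authoring format."""
    nodes_df = _read_csv(nodes_csv, ("name", "min", "max"), "nodes table")
    edges_df = _read_csv(edges_csv, ("source", "target", "sign"), "edges table")
    functions: dict[str, str] = {}
    if functions_csv is not None:
        fn_df = _read_csv(functions_csv, ("node", "expression"), "functions table")
        for i, row in fn_df.iterrows():
            functions[row["node"]] = row["expression"]

    node_names = set(nodes_df["name"])
    orphans = sorted(set(functions) - node_names)
    if orphans:
        raise FormatError(f"functions table: expression(s) for unknown node(s) {orphans}")

    nodes = []
    for i, row in nodes_df.iterrows():
        expr = functions.get(row["name"], "").strip()
        nodes.append(
            NodeDef(
                name=row["name"],
                min_level=_int_cell(row["min"], f"nodes table row {i}"),
                max_level=_int_cell(row["max"], f"nodes table row {i}"),
                target=expr or None,
                kind=row.get("kind", "protein") or "protein",
            )
        )
    edges = []
    for i, row in edges_df.iterrows():
        for endpoint in ("source", "target"):
            if row[endpoint] not in node_names:
                raise FormatError(
                    f"edges table row {i}: unknown node {row[endpoint]!r}"
                )
        edges.append(EdgeDef(row["source"], row["target"], _canon_sign(row["sign"], f"edges table row {i}")))

    network = QualitativeNetwork(nodes, edges, behavior_nodes=behavior_nodes, name=name)
    from .network import validate_network

    diags = validate_network(network)
    if diags:
        raise FormatError("invalid model: " + "; ".join(diags))
    return network


def write_model_tables(network: QualitativeNetwork, nodes_csv, edges_csv, functions_csv) -> None:
    pd.DataFrame(
        [
            {"name": n.name, "min": n.min_level, "max": n.max_level, "kind": n.kind}
            for n in network.nodes.values()
        ]
    ).to_csv(nodes_csv, index=False)
    pd.DataFrame(
        [{"source": e.source, "target": e.target, "sign": e.sign} for e in network.edges]
    ).to_csv(edges_csv, index=False)
    rows = []
    for n in network.nodes.values():
        if n.target is None or (isinstance(n.target, str) and n.target.strip().lower() == "default"):
            continue
        expr = n.target if isinstance(n.target, str) else n.target.unparse()
        rows.append({"node": n.name, "expression": expr})
    pd.DataFrame(rows, columns=["node", "expression"]).to_csv(functions_csv, index=False)


# ---------------------------------------------------------------------------
# Screen inputs: drugs, backgrounds, experiments
# ---------------------------------------------------------------------------


_PERT_TOKEN = re.compile(r"^(ko|oe|drug):([^=]+)$|^set:([^=]+)=(-?\d+)$")


def parse_perturbation_token(token: str, drugs: Mapping[str, DrugDef]) -> Perturbation:
    m = _PERT_TOKEN.match(token.strip())
    if m is None:
        raise FormatError(
            f"bad perturbation token {token!r} (expected ko:N, oe:N, set:N=L or drug:NAME)"
        )
    if m.group(3) is not None:
        return Perturbation.set_level(m.group(3).strip(), int(m.group(4)))
    kind, arg = m.group(1), m.group(2).strip()
    if kind == "ko":
        return Perturbation.knockout(arg)
    if kind == "oe":
        return Perturbation.overexpress(arg)
    if arg not in drugs:
        raise FormatError(f"perturbation references undefined drug {arg!r}")
    return Perturbation.of_drug(drugs[arg])


def _check_node(name: str, network: QualitativeNetwork | None, where: str) -> None:
    if network is not None and name not in network.nodes:
        raise FormatError(f"{where}: unknown node {name!r}")


def read_screen_tables(
    drugs_csv=None,
    backgrounds_csv=None,
    experiments_csv=None,
    network: QualitativeNetwork | None = None,
) -> tuple[list[DrugDef], list[Background], list[ExperimentRecord]]:
    """Read drug, background and experiment tables (any subset; pass None to
    skip one).  When ``network`` is supplied, every referenced node is
    cross-checked and levels are range-checked."""
    drugs: dict[str, DrugDef] = {}
    if drugs_csv is not None:
        df = _read_csv(drugs_csv, ("drug", "node", "level"), "drugs table")
        grouped: dict[str, list[tuple[str, int]]] = {}
        sources: dict[str, str] = {}
        for i, row in df.iterrows():
            where = f"drugs table row {i}"
            _check_node(row["node"], network, where)
            level = _int_cell(row["level"], where)
            if network is not None:
                node = network.nodes[row["node"]]
                if not (node.min_level <= level <= node.max_level):
                    raise FormatError(f"{where}: level {level} outside range {node.range}")
            grouped.setdefault(row["drug"], []).append((row["node"], level))
            if row.get("source", ""):
                sources[row["drug"]] = row["source"]
        drugs = {
            name: DrugDef(name, tuple(overrides), source=sources.get(name, ""))
            for name, overrides in grouped.items()
        }

    backgrounds: dict[str, Background] = {}
    if backgrounds_csv is not None:
        df = _read_csv(backgrounds_csv, ("background", "node", "level"), "backgrounds table")
        grouped = {}
        for i, row in df.iterrows():
            where = f"backgrounds table row {i}"
            _check_node(row["node"], network, where)
            level = _int_cell(row["level"], where)
            if network is not None:
                node = network.nodes[row["node"]]
                if not (node.min_level <= level <= node.max_level):
                    raise FormatError(f"{where}: level {level} outside range {node.range}")
            grouped.setdefault(row["background"], []).append((row["node"], level))
        backgrounds = {name: Background(name, tuple(clamps)) for name, clamps in grouped.items()}

    records: list[ExperimentRecord] = []
    if experiments_csv is not None:
        df = _read_csv(
            experiments_csv,
            ("id", "background", "perturbations", "readout", "expectation_kind", "expectation_value"),
            "experiments table",
        )
        by_id: dict[str, dict] = {}
        for i, row in df.iterrows():
            where = f"experiments table row {i}"
            if row["background"] not in backgrounds:
                raise FormatError(f"{where}: undefined background {row['background']!r}")
            _check_node(row["readout"], network, where)
            kind = row["expectation_kind"].strip()
            raw = row["expectation_value"].strip()
            if kind == "level":
                value: object = _int_cell(raw, where)
            elif kind == "range":
                m = re.match(r"^(-?\d+)\s*\.\.\s*(-?\d+)$", raw)
                if m is None:
                    raise FormatError(f"{where}: range expectation must look like 'lo..hi'")
                value = (int(m.group(1)), int(m.group(2)))
            elif kind == "direction":
                value = raw
            else:
                raise FormatError(f"{where}: unknown expectation kind {kind!r}")
            perts = tuple(
                parse_perturbation_token(tok, drugs)
                for tok in row["perturbations"].split(";")
                if tok.strip()
            )
            entry = by_id.setdefault(
                row["id"],
                {"background": backgrounds[row["background"]], "perturbations": perts, "measurements": []},
            )
            entry["measurements"].append(Measurement(row["readout"], kind, value))
        for rec_id, entry in by_id.items():
            records.append(
                ExperimentRecord(
                    id=rec_id,
                    background=entry["background"],
                    perturbations=entry["perturbations"],
                    measurements=tuple(entry["measurements"]),
                )
            )
    return list(drugs.values()), list(backgrounds.values()), records


def write_experiments_csv(records: Sequence[ExperimentRecord], experiments_csv, backgrounds_csv=None) -> None:
    """Emit experiment records (and their backgrounds) in the CSV schema that
    :func:`read_screen_tables` consumes."""
    rows = []
    bg_rows = []
    seen_bg = set()
    for rec in records:
        if rec.background.name not in seen_bg:
            seen_bg.add(rec.background.name)
            for node, level in rec.background.clamps:
                bg_rows.append({"background": rec.background.name, "node": node, "level": level})
            if not rec.background.clamps:
                # background with no clamps still needs to exist; emit nothing
                pass
        perts = ";".join(p.label for p in rec.perturbations)
        for m in rec.measurements:
            if m.kind == "range":
                value = f"{m.value[0]}..{m.value[1]}"
            else:
                value = str(m.value)
            rows.append(
                {
                    "id": rec.id,
                    "background": rec.background.name,
                    "perturbations": perts,
                    "readout": m.readout,
                    "expectation_kind": m.kind,
                    "expectation_value": value,
                }
            )
    pd.DataFrame(rows).to_csv(experiments_csv, index=False)
    if backgrounds_csv is not None:
        pd.DataFrame(bg_rows, columns=["background", "node", "level"]).to_csv(
            backgrounds_csv, index=False
        )
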