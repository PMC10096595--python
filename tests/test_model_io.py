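"""Serialization: BMA JSON, tabular model format, screen tables."""

import json

import pytest

from qnsim import NodeDef, QualitativeNetwork, model_io
from qnsim.model_io import FormatError


def networks_equivalent(a: QualitativeNetwork, b: QualitativeNetwork) -> bool:
    if set(a.nodes) != set(b.nodes) or a.behavior_nodes != b.behavior_nodes:
        return False
    for name in a.nodes:
        na, nb = a.nodes[name], b.nodes[name]
        if (na.range, na.kind) != (nb.range, nb.kind):
            return False
        if a.compiled_target(name) != b.compiled_target(name):
            return False
    return sorted((e.source, e.target, e.sign) for e in a.edges) == sorted(
        (e.source, e.target, e.sign) for e in b.edges
    )


MINIMAL_BMA = {
    "Model": {
        "Name": "tiny",
        "Variables": [
            {"Id": 1, "Name": "A", "RangeFrom": 0, "RangeTo": 2, "Formula": ""},
            {"Id": 2, "Name": "B", "RangeFrom": 0, "RangeTo": 2, "Formula": ""},
        ],
        "Relationships": [
            {"Id": 3, "FromVariable": 1, "ToVariable": 2, "Type": "Activator"}
        ],
    }
}


class TestBmaJson:
    def test_minimal_document(self):
        net = model_io.read_bma_json(MINIMAL_BMA)
        assert len(net.nodes) == 2 and len(net.edges) == 1
        assert net.edges[0].source == "A" and net.edges[0].sign == "activating"

    def test_constant_formula(self):
        doc = json.loads(json.dumps(MINIMAL_BMA))
        doc["Model"]["Variables"][0]["Formula"] = "2"
        net = model_io.read_bma_json(doc)
        from qnsim import evaluate_target

        assert evaluate_target("A", {"A": 0, "B": 0}, net) == 2

    def test_numeric_var_ids_translated(self):
        doc = json.loads(json.dumps(MINIMAL_BMA))
        doc["Model"]["Variables"][1]["Formula"] = "var(1) + 1"
        net = model_io.read_bma_json(doc)
        assert "var(A)" in net.compiled_target("B").unparse()

    def test_missing_key_names_json_path(self):
        doc = {"Model": {"Variables": [{"Id": 1, "Name": "A", "RangeFrom": 0}]}}
        with pytest.raises(FormatError, match=r"\$\.Model\.Variables\[0\]\.RangeTo"):
            model_io.read_bma_json(doc)

    def test_unknown_relationship_type(self):
        doc = json.loads(json.dumps(MINIMAL_BMA))
        doc["Model"]["Relationships"][0]["Type"] = "Mystery"
        with pytest.raises(FormatError, match="Mystery"):
            model_io.read_bma_json(doc)

    def test_round_trip_identity(self, demo_model, tmp_path):
        path = tmp_path / "model.json"
        model_io.write_bma_json(demo_model, path)
        again = model_io.read_bma_json(path)
        assert networks_equivalent(demo_model, again)

    def test_write_is_canonical_and_layout_preserved(self, tnf_autocrine, tmp_path):
        layout = {"Variables": [{"Id": 1, "PositionX": 10}]}
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        model_io.write_bma_json(tnf_autocrine, p1, layout=layout)
        doc = model_io.read_bma_document(p1)
        assert doc.layout == layout
        model_io.write_bma_json(doc.network, p2, layout=doc.layout)
        assert p1.read_bytes() == p2.read_bytes()


class TestModelTables:
    def test_round_trip(self, demo_model, tmp_path):
        paths = [tmp_path / n for n in ("nodes.csv", "edges.csv", "functions.csv")]
        model_io.write_model_tables(demo_model, *paths)
        again = model_io.read_model_tables(*paths, behavior_nodes=demo_model.behavior_nodes)
        assert networks_equivalent(demo_model, again)

    def test_regulator_free_network_with_constant_functions(self, tmp_path):
        (tmp_path / "nodes.csv").write_text("name,min,max,kind\nA,0,2,protein\nB,0,1,gene\n")
        (tmp_path / "edges.csv").write_text("source,target,sign\n")
        (tmp_path / "functions.csv").write_text('node,expression\nA,2\nB,1\n')
        net = model_io.read_model_tables(
            tmp_path / "nodes.csv", tmp_path / "edges.csv", tmp_path / "functions.csv"
        )
        assert len(net.nodes) == 2 and len(net.edges) == 0

    def test_function_for_unknown_node_lists_offender(self, tmp_path):
        (tmp_path / "nodes.csv").write_text("name,min,max\nA,0,2\n")
        (tmp_path / "edges.csv").write_text("source,target,sign\n")
        (tmp_path / "functions.csv").write_text("node,expression\nGHOST,2\n")
        with pytest.raises(FormatError, match="GHOST"):
            model_io.read_model_tables(
                tmp_path / "nodes.csv", tmp_path / "edges.csv", tmp_path / "functions.csv"
            )

    def test_malformed_level_rejected_not_coerced(self, tmp_path):
        (tmp_path / "nodes.csv").write_text("name,min,max\nA,0,two\n")
        (tmp_path / "edges.csv").write_text("source,target,sign\n")
        with pytest.raises(FormatError, match="not an integer"):
            model_io.read_model_tables(tmp_path / "nodes.csv", tmp_path / "edges.csv")


class TestScreenTables:
    def write_inputs(self, tmp_path):
        (tmp_path / "drugs.csv").write_text(
            "drug,node,level\nblocker,TNFR,0\nblocker,TF,0\nagonist,TNF,2\n"
        )
        (tmp_path / "backgrounds.csv").write_text(
            "background,node,level\nhealthy,TNF,0\nengaged,TNF,2\n"
        )
        (tmp_path / "experiments.csv").write_text(
            "id,background,perturbations,readout,expectation_kind,expectation_value\n"
            "e1,healthy,,Residency_LC,level,2\n"
            "e2,healthy,drug:agonist,Residency_LC,direction,decrease\n"
            "e3,engaged,ko:TF;oe:TNFR,TNF,range,0..2\n"
        )

    def test_reads_and_cross_checks(self, tmp_path, tnf_autocrine):
        self.write_inputs(tmp_path)
        drugs, backgrounds, records = model_io.read_screen_tables(
            tmp_path / "drugs.csv",
            tmp_path / "backgrounds.csv",
            tmp_path / "experiments.csv",
            network=tnf_autocrine,
        )
        assert {d.name for d in drugs} == {"blocker", "agonist"}
        assert dict(next(d for d in drugs if d.name == "blocker").overrides) == {
            "TNFR": 0,
            "TF": 0,
        }
        assert {b.name for b in backgrounds} == {"healthy", "engaged"}
        assert len(records) == 3
        rec2 = next(r for r in records if r.id == "e2")
        assert rec2.perturbations[0].kind == "drug"

    def test_undefined_background_rejected(self, tmp_path, tnf_autocrine):
        self.write_inputs(tmp_path)
        (tmp_path / "experiments.csv").write_text(
            "id,background,perturbations,readout,expectation_kind,expectation_value\n"
            "e1,nonexistent,,TNF,level,0\n"
        )
        with pytest.raises(FormatError, match="nonexistent"):
            model_io.read_screen_tables(
                backgrounds_csv=tmp_path / "backgrounds.csv",
                experiments_csv=tmp_path / "experiments.csv",
                network=tnf_autocrine,
            )

    def test_clamp_on_unknown_node_names_row(self, tmp_path, tnf_autocrine):
        (tmp_path / "drugs.csv").write_text("drug,node,level\nmystery,GHOST,0\n")
        with pytest.raises(FormatError, match="row 0"):
            model_io.read_screen_tables(tmp_path / "drugs.csv", network=tnf_autocrine)

    def test_out_of_range_clamp_rejected(self, tmp_path, tnf_autocrine):
        (tmp_path / "drugs.csv").write_text("drug,node,level\ntoomuch,TNF,9\n")
        with pytest.raises(FormatError, match="outside range"):
            model_io.read_screen_tables(tmp_path / "drugs.csv", network=tnf_autocrine)

    def test_experiment_round_trip(self, tmp_path, tnf_autocrine):
        from qnsim import synthetic

        records, _ = synthetic.generate_experiment_set(tnf_autocrine, 5, seed=7)
        model_io.write_experiments_csv(
            records, tmp_path / "exp.csv", tmp_path / "bg.csv"
        )
        _, _, again = model_io.read_screen_tables(
            backgrounds_csv=tmp_path / "bg.csv",
            experiments_csv=tmp_path / "exp.csv",
            network=tnf_autocrine,
        )
        assert {r.id for r in again} == {r.id for r in records}
        by_id = {r.id: r for r in again}
        for r in records:
            assert by_id[r.id].measurements == r.measurements
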