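"""Perturbations, backgrounds, screens, growth score, combination ranking."""

from fractions import Fraction

import pytest

from qnsim import (
    Background,
    DrugDef,
    NetworkError,
    Perturbation,
    apply_perturbation,
    bound_stable_states,
    run_screen,
    select_optimal_combinations,
    summarize_level,
    tumor_growth_score,
)

F = Fraction


class TestApplyPerturbation:
    def test_knockout_forces_minimum(self, tnf_autocrine):
        net = apply_perturbation(tnf_autocrine, Perturbation.knockout("TNF"))
        bounds = bound_stable_states(net)
        assert bounds["TNF"] == (0, 0)

    def test_set_level_singleton(self, tnf_autocrine):
        net = apply_perturbation(tnf_autocrine, Perturbation.set_level("TNF", 2))
        assert bound_stable_states(net)["TNF"] == (2, 2)

    def test_overexpress_forces_maximum(self, tnf_autocrine):
        net = apply_perturbation(tnf_autocrine, Perturbation.overexpress("TF"))
        assert bound_stable_states(net)["TF"] == (2, 2)

    def test_disjoint_perturbations_commute(self, tnf_autocrine):
        p1, p2 = Perturbation.knockout("TF"), Perturbation.set_level("TNFR", 1)
        a = apply_perturbation(apply_perturbation(tnf_autocrine, p1), p2)
        b = apply_perturbation(apply_perturbation(tnf_autocrine, p2), p1)
        ba, bb = bound_stable_states(a), bound_stable_states(b)
        assert ba.bounds == bb.bounds

    def test_same_node_is_last_write_wins(self, tnf_autocrine):
        net = apply_perturbation(tnf_autocrine, Perturbation.knockout("TNF"))
        net = apply_perturbation(net, Perturbation.overexpress("TNF"))
        assert bound_stable_states(net)["TNF"] == (2, 2)

    def test_unknown_node_rejected(self, tnf_autocrine):
        with pytest.raises(NetworkError):
            apply_perturbation(tnf_autocrine, Perturbation.knockout("GHOST"))

    def test_drug_expands_to_overrides(self, tnf_autocrine):
        drug = DrugDef("blocker", (("TNFR", 0), ("TF", 0)))
        net = apply_perturbation(tnf_autocrine, Perturbation.of_drug(drug))
        bounds = bound_stable_states(net)
        assert bounds["TNFR"] == (0, 0) and bounds["TF"] == (0, 0)
        # with the receptor dead the loop cannot engage
        assert bounds.proven_unique and bounds["TNF"] == (0, 0)


class TestTumorGrowthScore:
    def test_difference(self):
        assert tumor_growth_score({"Proliferation": F(2), "Apoptosis": F(1)}) == F(1)

    def test_equal_levels_zero(self):
        assert tumor_growth_score({"Proliferation": F(1), "Apoptosis": F(1)}) == F(0)

    def test_midpoint_readouts(self):
        assert tumor_growth_score({"Proliferation": F(3, 2), "Apoptosis": F(1, 2)}) == F(1)

    def test_missing_readout_errors(self):
        with pytest.raises(NetworkError):
            tumor_growth_score({"Proliferation": F(1)})


class TestRunScreen:
    def test_empty_perturbation_list_gives_baselines_only(self, tnf_autocrine):
        bgs = [Background("off", (("TNF", 0),)), Background("on", (("TNF", 2),))]
        res = run_screen(tnf_autocrine, bgs, (), readouts=("Residency_LC",))
        assert len(res.table) == 2
        assert set(res.table["background"]) == {"off", "on"}
        assert (res.table["perturbation_1"] == "").all()

    def test_pairwise_combinatorics(self, tnf_autocrine):
        bgs = [Background("b", (("TNF", 0),))]
        perts = [Perturbation.knockout(n) for n in ("TF", "TNFR", "Residency_LC")]
        res = run_screen(tnf_autocrine, bgs, perts, readouts=("TNF",), pairwise=True)
        # 1 baseline + 3 singles + 3 pairs
        assert len(res.table) == 7
        pairs = res.table[res.table["perturbation_2"] != ""]
        assert len(pairs) == 3
        # pairs are canonically ordered
        assert (pairs["perturbation_1"] < pairs["perturbation_2"]).all()

    def test_clamped_node_reports_its_clamp_under_any_perturbation(self, tnf_autocrine):
        bgs = [Background("b", (("TNFR", 1),))]
        perts = [Perturbation.knockout("TF")]
        res = run_screen(tnf_autocrine, bgs, perts, readouts=("TNFR",))
        assert (res.table["TNFR"] == F(1)).all()

    def test_result_invariant_to_job_order(self, tnf_autocrine):
        bgs = [Background("x", (("TNF", 0),)), Background("y", (("TNF", 2),))]
        perts = [Perturbation.knockout("TF"), Perturbation.overexpress("TNFR")]
        a = run_screen(tnf_autocrine, bgs, perts, readouts=("Residency_LC",))
        b = run_screen(tnf_autocrine, list(reversed(bgs)), perts, readouts=("Residency_LC",))
        key = ["background", "perturbation_1", "perturbation_2"]
        ta = a.table.sort_values(key).reset_index(drop=True)
        tb = b.table.sort_values(key).reset_index(drop=True)
        assert ta.equals(tb)

    def test_growth_score_column_present_iff_both_readouts(self, demo_model, demo_backgrounds):
        with_both = run_screen(demo_model, demo_backgrounds[:1],
                               readouts=("Proliferation", "Apoptosis"))
        assert "tumor_growth_score" in with_both.table.columns
        without = run_screen(demo_model, demo_backgrounds[:1], readouts=("Proliferation",))
        assert "tumor_growth_score" not in without.table.columns

    def test_requires_backgrounds(self, tnf_autocrine):
        with pytest.raises(NetworkError):
            run_screen(tnf_autocrine, [], ())

    def test_unknown_readout_rejected(self, tnf_autocrine):
        with pytest.raises(NetworkError, match="GHOST"):
            run_screen(tnf_autocrine, [Background("b")], (), readouts=("GHOST",))


class TestDemoModelScreen:
    def test_healthy_and_mitf_low_differ_in_tnf(self, demo_model, demo_backgrounds):
        """The dedifferentiated (MITF-low) background locks the autocrine
        loop on; healthy skin never engages it."""
        res = run_screen(demo_model, demo_backgrounds, (), readouts=("TNF",))
        healthy = res.row("healthy")["TNF"]
        mitf_low = res.row("BRAF_MITFlow")["TNF"]
        assert healthy == F(0) and mitf_low == F(2)
        assert healthy != mitf_low

    def test_select_optimal_filters_residency_raisers(self, demo_model, demo_backgrounds, demo_drugs):
        perts = [Perturbation.of_drug(d) for d in demo_drugs]
        res = run_screen(demo_model, demo_backgrounds, perts,
                         readouts=demo_model.behavior_nodes, pairwise=True)
        ranked = select_optimal_combinations(res, "Residency_LC")
        assert not ranked.empty
        # scores come out sorted ascending (best = most growth-suppressive first)
        scores = list(ranked["score"])
        assert scores == sorted(scores)
        # pairs of two MAPK inhibitors raise residency in the MITF-high
        # backgrounds and must have been filtered out (a MAPK inhibitor
        # rescued by a residency-lowering TGF-beta drug may survive)
        mapki = {"drug:dabrafenib", "drug:trametinib", "drug:ulixertinib"}
        pure_mapki_pairs = [
            (p1, p2)
            for p1, p2 in zip(ranked["perturbation_1"], ranked["perturbation_2"])
            if p1 in mapki and p2 in mapki
        ]
        assert pure_mapki_pairs == []

    def test_residency_node_must_be_a_readout(self, demo_model, demo_backgrounds):
        res = run_screen(demo_model, demo_backgrounds[:1], (), readouts=("TNF",))
        with pytest.raises(NetworkError):
            select_optimal_combinations(res, "Residency_LC")
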