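"""Synthetic generators: motifs, random networks, oracle-labelled experiments."""

import pytest

from qnsim import (
    enumerate_attractors,
    score_experiments,
    validate_network,
)
from qnsim import synthetic
from qnsim.network import NetworkError


class TestMotifs:
    @pytest.mark.parametrize("name", synthetic.MOTIFS)
    def test_all_motifs_validate(self, name):
        assert validate_network(synthetic.make_motif(name)) == []

    @pytest.mark.parametrize("max_level", [1, 2])
    def test_autocrine_loop_bistable_at_both_ranges(self, max_level):
        """The positive-feedback switch has exactly two attractors (loop off /
        loop on) whether nodes are Boolean or three-level."""
        net = synthetic.make_motif("tnf_autocrine", max_level=max_level)
        ats = enumerate_attractors(net)
        assert len(ats) == 2
        assert all(a.is_fixed_point for a in ats)
        tnf = sorted(a.states[0]["TNF"] for a in ats)
        assert tnf == [0, max_level]

    def test_autocrine_high_state_abolishes_residency(self):
        net = synthetic.make_motif("tnf_autocrine", max_level=2)
        high = next(
            a for a in enumerate_attractors(net) if a.states[0]["TNF"] == 2
        )
        assert high.states[0]["Residency_LC"] == 0

    def test_autocrine_contains_positive_cycle(self):
        import networkx as nx

        net = synthetic.make_motif("tnf_autocrine")
        g = nx.DiGraph(
            (e.source, e.target)
            for e in net.edges
            if e.sign == "activating"
        )
        assert any(len(c) > 1 for c in nx.simple_cycles(g))

    def test_clamping_ligand_collapses_to_one_attractor(self):
        """Forcing the ligand at maximum locks the loop on: the synthetic
        analogue of the dedifferentiated state."""
        net = synthetic.make_motif("tnf_autocrine", max_level=2)
        assert len(enumerate_attractors(net.with_targets({"TNF": 2}))) == 1

    def test_clamped_cascade_unique(self):
        from qnsim import bound_stable_states

        net = synthetic.make_motif("linear_cascade", cascade_length=3)
        clamped = net.with_targets({"In": 2})
        assert bound_stable_states(clamped).proven_unique
        assert len(enumerate_attractors(clamped)) == 1

    def test_unknown_motif(self):
        with pytest.raises(NetworkError, match="unknown motif"):
            synthetic.make_motif("nonsense")


class TestRandomNetworks:
    def test_same_seed_identical(self):
        a = synthetic.generate_random_network(6, 0.4, max_range=2, seed=11)
        b = synthetic.generate_random_network(6, 0.4, max_range=2, seed=11)
        assert [(n.name, n.range) for n in a.nodes.values()] == [
            (n.name, n.range) for n in b.nodes.values()
        ]
        assert a.edges == b.edges

    def test_different_seeds_differ(self):
        a = synthetic.generate_random_network(8, 0.4, seed=1)
        b = synthetic.generate_random_network(8, 0.4, seed=2)
        assert a.edges != b.edges or [n.range for n in a.nodes.values()] != [
            n.range for n in b.nodes.values()
        ]

    def test_always_valid(self):
        for seed in range(10):
            net = synthetic.generate_random_network(5, 0.5, max_range=3, seed=seed)
            assert validate_network(net) == []

    def test_boolean_special_case(self):
        net = synthetic.generate_random_network(5, 0.5, max_range=1, seed=3)
        assert all(n.range == (0, 1) for n in net.nodes.values())

    def test_parameter_validation(self):
        with pytest.raises(NetworkError):
            synthetic.generate_random_network(0, 0.5)
        with pytest.raises(NetworkError):
            synthetic.generate_random_network(3, 0.0)


class TestExperimentSets:
    def test_uncorrupted_set_validates_at_100_percent(self, tnf_autocrine):
        records, corrupted = synthetic.generate_experiment_set(
            tnf_autocrine, 12, seed=5
        )
        assert corrupted == []
        report = score_experiments(tnf_autocrine, records)
        assert report.n_pass == report.n_total == 12

    def test_corruption_fails_exactly_the_corrupted_measurements(self, tnf_autocrine):
        records, corrupted = synthetic.generate_experiment_set(
            tnf_autocrine, 10, seed=5, corrupt_fraction=0.2
        )
        assert len(corrupted) == 2
        report = score_experiments(tnf_autocrine, records)
        assert report.n_total == 10
        assert report.n_pass == 8
        assert sorted(v.experiment_id for v in report.failures()) == sorted(corrupted)

    def test_same_seed_identical_records(self, tnf_autocrine):
        a, _ = synthetic.generate_experiment_set(tnf_autocrine, 6, seed=9)
        b, _ = synthetic.generate_experiment_set(tnf_autocrine, 6, seed=9)
        assert a == b

    def test_refuses_large_networks(self):
        big = synthetic.generate_random_network(30, 0.2, max_range=2, seed=0)
        with pytest.raises(NetworkError, match="too large"):
            synthetic.generate_experiment_set(big, 3, seed=0)


class TestDemoModel:
    def test_validates_and_has_behavior_nodes(self, demo_model):
        assert validate_network(demo_model) == []
        assert "Residency_LC" in demo_model.behavior_nodes
        assert "Proliferation" in demo_model.behavior_nodes

    def test_backgrounds_clamp_only_known_nodes(self, demo_model, demo_backgrounds):
        assert len(demo_backgrounds) == 5  # four mutant contexts + healthy control
        for bg in demo_backgrounds:
            for node, level in bg.clamps:
                nd = demo_model.nodes[node]
                assert nd.min_level <= level <= nd.max_level

    def test_drug_panel_targets_known_nodes(self, demo_model, demo_drugs):
        for drug in demo_drugs:
            for node, level in drug.overrides:
                nd = demo_model.nodes[node]
                assert nd.min_level <= level <= nd.max_level
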