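"""Fault injection, symptom labeling, observation selection and batches."""

from __future__ import annotations

import numpy as np
import pytest

import physdx as px
from physdx.errors import ConfigError, GenerationError
from physdx.simulate import SimulationConfig


class TestInjectFaults:
    def test_never_selects_a_dermatome(self, toy_chain):
        rng = np.random.default_rng(0)
        for _ in range(50):
            faults = px.inject_faults(toy_chain, 1, rng)
            assert faults <= {"R1", "N1", "M1"}

    def test_full_cardinality_selects_everything(self, toy_chain):
        faults = px.inject_faults(toy_chain, 3, np.random.default_rng(1))
        assert faults == {"R1", "N1", "M1"}

    def test_deterministic_per_seed(self, synth75):
        a = px.inject_faults(synth75, 4, np.random.default_rng(9))
        b = px.inject_faults(synth75, 4, np.random.default_rng(9))
        assert a == b

    def test_out_of_range_cardinality_rejected(self, toy_chain):
        with pytest.raises(ConfigError):
            px.inject_faults(toy_chain, 4, np.random.default_rng(0))


class TestSharedAffectingComponent:
    def test_diamond_nerves_share_their_root(self, toy_diamond):
        assert px.has_shared_affecting_component(toy_diamond, {"N1", "N2"})

    def test_singleton_never_entangled(self, toy_diamond):
        assert not px.has_shared_affecting_component(toy_diamond, {"N1"})

    def test_disjoint_root_trees_are_disentangled(self):
        m = px.AnatomyModel(
            [
                px.Component("R1", "r1", px.ComponentKind.NERVE_ROOT),
                px.Component("R2", "r2", px.ComponentKind.NERVE_ROOT),
                px.Component("M1", "m1", px.ComponentKind.MUSCLE),
                px.Component("M2", "m2", px.ComponentKind.MUSCLE),
            ],
            [("R1", "M1"), ("R2", "M2")],
        )
        assert not px.has_shared_affecting_component(m, {"M1", "M2"})

    def test_fault_affecting_another_fault_counts_as_shared(self, toy_chain):
        assert px.has_shared_affecting_component(toy_chain, {"R1", "M1"})


class TestLabelSymptoms:
    def test_relaxed_mode_fails_exactly_the_affected_set(self, toy_chain):
        labels = px.label_symptoms(
            toy_chain, {"N1"}, 1.0, np.random.default_rng(0)
        )
        # D1 hangs off R1, not N1, so it stays healthy
        assert {c for c, ok in labels.items() if not ok} == {"N1", "M1"}

    def test_half_probability_respects_affected_bounds(self, toy_chain):
        for seed in range(20):
            labels = px.label_symptoms(
                toy_chain, {"N1"}, 0.5, np.random.default_rng(seed)
            )
            failing = {c for c, ok in labels.items() if not ok}
            assert failing <= {"N1", "M1"}
            assert failing  # forced explaining symptom

    def test_unaffected_components_always_pass(self, toy_chain):
        labels = px.label_symptoms(
            toy_chain, {"M1"}, 1.0, np.random.default_rng(3)
        )
        assert labels["R1"] and labels["N1"] and labels["D1"]
        assert not labels["M1"]

    def test_every_fault_gets_an_explaining_symptom(self, synth75):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            faults = px.inject_faults(synth75, 3, rng)
            labels = px.label_symptoms(synth75, faults, 0.2, rng)
            for f in faults:
                down = {f} | synth75.descendants(f)
                assert any(not labels[c] for c in down)


class TestSelectObservations:
    def test_size_capped_by_cardinality_and_failures(self):
        labels = {f"c{i}": False for i in range(6)}
        for seed in range(25):
            obs = px.select_observations(labels, 4, np.random.default_rng(seed))
            assert 1 <= len(obs) <= 4
            assert all(v is False for v in obs.values())

    def test_single_fault_gives_single_observation(self):
        labels = {"a": False, "b": False, "c": True}
        obs = px.select_observations(labels, 1, np.random.default_rng(0))
        assert len(obs) == 1 and set(obs) <= {"a", "b"}

    def test_no_failures_is_a_contract_violation(self):
        with pytest.raises(ConfigError):
            px.select_observations({"a": True}, 1, np.random.default_rng(0))


class TestGenerateScenario:
    def test_invariants_hold(self, synth75):
        for seed in range(25):
            k = 1 + seed % 5
            sc = px.generate_scenario(synth75, k, 0.5, seed=seed)
            dermatomes = set(synth75.dermatome_ids)
            assert not (sc.faults & dermatomes)
            affected = set()
            for f in sc.faults:
                affected |= {f} | synth75.descendants(f)
            failing = {c for c, ok in sc.labels.items() if not ok}
            assert failing <= affected
            for f in sc.faults:
                assert ({f} | synth75.descendants(f)) & failing
            assert 1 <= len(sc.initial_obs) <= len(sc.faults)
            assert all(not sc.labels[c] for c in sc.initial_obs)

    def test_relaxed_fragment_fault_fails_entire_closure(self, fragment):
        sc = px.generate_scenario(fragment, 1, 1.0, seed=2, faults=["C6"])
        failing = {c for c, ok in sc.labels.items() if not ok}
        assert failing == {"C6"} | fragment.descendants("C6")

    def test_deterministic_per_seed(self, synth75):
        assert px.generate_scenario(synth75, 3, 0.5, seed=77) == px.generate_scenario(
            synth75, 3, 0.5, seed=77
        )

    def test_entangled_model_exhausts_retries(self, toy_diamond):
        # every 2-fault draw in the diamond shares the root R1
        with pytest.raises(GenerationError):
            px.generate_scenario(toy_diamond, 2, 0.5, seed=0, max_retries=50)

    def test_initial_diagnosis_is_informative(self, synth75):
        """Each failed initial observation's closure contains a true fault,
        so diagnosing the initial observations can never come up empty."""
        for seed in range(15):
            sc = px.generate_scenario(synth75, 3, 0.5, seed=seed)
            D = px.diagnose(synth75, sc.initial_obs)
            assert len(D) >= 1
            for c in sc.initial_obs:
                assert synth75.closure(c) & sc.faults


class TestGenerateBatch:
    def test_default_config_counts_and_reproducibility(self, synth75):
        cfg = SimulationConfig(seed=123, instances_per_cardinality=5)
        a = px.generate_batch(synth75, cfg)
        b = px.generate_batch(synth75, cfg)
        assert a.scenarios == b.scenarios
        n_singles = len(synth75.faultable_ids)
        assert a.n_requested == n_singles + 5 * 5
        assert len(a.scenarios) == a.n_requested  # retry mode reaches size
        singles = [s for s in a.scenarios if s.cardinality == 1]
        assert {next(iter(s.faults)) for s in singles[:n_singles]} == set(
            synth75.faultable_ids
        )

    def test_filter_mode_discards_entangled_draws(self, toy_diamond):
        cfg = SimulationConfig(
            cardinality_range=(2, 2),
            instances_per_cardinality=20,
            singles_exhaustive=False,
            discard_mode="filter",
            seed=0,
        )
        out = px.generate_batch(toy_diamond, cfg)
        # {N1,N2}, {N1,M1}... every pair shares a closure member via R1 or M1
        assert out.n_discarded == 20
        assert out.scenarios == []

    def test_batch_faults_are_pairwise_disjoint_closures(self, synth75):
        cfg = SimulationConfig(seed=3, instances_per_cardinality=4)
        out = px.generate_batch(synth75, cfg)
        for sc in out.scenarios:
            assert not px.has_shared_affecting_component(synth75, sc.faults)

    def test_cardinality_beyond_faultable_count_rejected(self, toy_chain):
        cfg = SimulationConfig(cardinality_range=(2, 9))
        with pytest.raises(ConfigError):
            px.generate_batch(toy_chain, cfg)


class TestOracleAndIO:
    def test_oracle_answers_from_labels_consistently(self, toy_chain):
        sc = px.generate_scenario(toy_chain, 1, 1.0, seed=4, faults=["N1"])
        oracle = px.oracle_from_scenario(sc)
        assert oracle("N1") is False
        assert oracle("N1") is False
        assert oracle("R1") is True  # unaffected passes

    def test_jsonl_roundtrip(self, synth75, tmp_path):
        scenarios = [
            px.generate_scenario(synth75, 2, 0.5, seed=s) for s in range(4)
        ]
        path = tmp_path / "scenarios.jsonl"
        px.save_scenarios(scenarios, path)
        assert px.load_scenarios(path) == scenarios

    def test_config_file_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "cardinality_range: [2, 4]\nfail_prob: 1.0\nseed: 9\n"
            "instances_per_cardinality: 10\n"
        )
        cfg = SimulationConfig.from_file(path)
        assert cfg.cardinality_range == (2, 4)
        assert cfg.fail_prob == 1.0

    def test_unknown_config_key_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("nope: 1\n")
        with pytest.raises(ConfigError):
            SimulationConfig.from_file(bad)
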