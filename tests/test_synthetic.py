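"""Synthetic cohort generator: determinism, planted structure, outcomes."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sparenet import ConfigError, GeneratorConfig, generate_cohort, generate_controls
from sparenet.synthetic import (
    OutcomeCoefs,
    assign_outcomes,
    build_scaffold,
    generate_clinical,
    generate_patient,
    make_node_table,
)


class TestConfig:
    @pytest.mark.parametrize("field,value", [
        ("n_nodes", 15), ("edge_dropout", 1.5), ("scaffold_density", -0.1),
        ("resection_area", "insula"), ("planted_sign", 0),
        ("gfa_mean_range", (0.0, 0.5)),
    ])
    def test_invalid_values_name_the_field(self, field, value):
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            GeneratorConfig(**{field: value})

    def test_node_table_structure(self):
        nodes = make_node_table(114)
        assert len(nodes) == 114
        assert (nodes.groupby("hemisphere").size() == 57).all()
        assert set(nodes["area"]) == {
            "temporal", "subcortical", "parietal", "occipital", "frontal", "cingulate"}
        nodes82 = make_node_table(82)
        assert len(nodes82) == 82


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        cfg = GeneratorConfig(n_nodes=20, n_controls=5, n_patients=6, seed=1)
        a = generate_cohort(cfg)
        b = generate_cohort(GeneratorConfig(n_nodes=20, n_controls=5, n_patients=6,
                                            seed=1))
        for ca, cb in zip(a.controls, b.controls):
            np.testing.assert_array_equal(ca.gfa, cb.gfa)
            np.testing.assert_array_equal(ca.streamlines, cb.streamlines)
        for pa, pb in zip(a.patients, b.patients):
            np.testing.assert_array_equal(pa.gfa, pb.gfa)
        assert [e.affected for e in a.effects] == [e.affected for e in b.effects]
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)

    def test_different_seed_differs(self):
        a = generate_cohort(GeneratorConfig(n_nodes=20, n_controls=3, n_patients=3,
                                            seed=1))
        b = generate_cohort(GeneratorConfig(n_nodes=20, n_controls=3, n_patients=3,
                                            seed=2))
        assert not np.array_equal(a.controls[0].gfa, b.controls[0].gfa,
                                  equal_nan=True)


class TestControls:
    def test_zero_dropout_gives_full_scaffold(self):
        cfg = GeneratorConfig(n_nodes=20, n_controls=4, edge_dropout=0.0, seed=2)
        rng = np.random.default_rng(0)
        scaffold = build_scaffold(cfg, rng)
        controls = generate_controls(cfg, scaffold=scaffold, rng=rng)
        for c in controls:
            np.testing.assert_array_equal(c.present, scaffold.edges)

    def test_presence_matches_binomial_expectation(self):
        cfg = GeneratorConfig(n_nodes=30, n_controls=40, edge_dropout=0.3, seed=4)
        rng = np.random.default_rng(1)
        scaffold = build_scaffold(cfg, rng)
        controls = generate_controls(cfg, scaffold=scaffold, rng=rng)
        presence = sum(c.present for c in controls)[np.triu(scaffold.edges, 1)]
        expected = cfg.n_controls * (1 - cfg.edge_dropout)
        # mean over ~400 edges: binomial SE of the mean is tiny
        se = np.sqrt(cfg.n_controls * 0.3 * 0.7 / presence.size)
        assert abs(presence.mean() - expected) < 4 * se

    def test_gfa_within_unit_interval(self):
        cfg = GeneratorConfig(n_nodes=20, n_controls=5, seed=6)
        for c in generate_controls(cfg):
            vals = c.gfa[c.present]
            assert ((vals > 0) & (vals < 1)).all()


class TestPatients:
    def _setup(self, **kw):
        cfg = GeneratorConfig(n_nodes=24, n_controls=4, seed=8, **kw)
        rng = np.random.default_rng(3)
        scaffold = build_scaffold(cfg, rng)
        return cfg, scaffold, rng

    def test_planted_outside_parcellation_error(self):
        cfg, scaffold, rng = self._setup()
        with pytest.raises(ValueError, match="parcellation"):
            generate_patient(cfg, scaffold, ["nope"], rng)

    def test_planted_edges_incident_to_planted_nodes(self):
        cfg, scaffold, rng = self._setup()
        planted = scaffold.nodes["label"].iloc[:3].tolist()
        _, _, truth = generate_patient(cfg, scaffold, planted, rng)
        for a, b in truth.planted_edges:
            assert a in planted or b in planted

    def test_planted_inside_resection_spares_nothing(self):
        cfg, scaffold, rng = self._setup(passthrough_fraction=0.0)
        inside = scaffold.nodes.loc[
            (scaffold.nodes["hemisphere"] == "left")
            & (scaffold.nodes["area"] == "temporal"), "label"].tolist()
        _, _, truth = generate_patient(cfg, scaffold, inside[:3], rng,
                                       surgery_side="left")
        assert truth.true_spared_load == 0

    def test_zero_effect_matches_control_distribution(self):
        cfg, scaffold, rng = self._setup(planted_effect=0.0)
        planted = scaffold.nodes["label"].iloc[:3].tolist()
        patient, _, _ = generate_patient(cfg, scaffold, planted, rng)
        # planted edges should sit within the control population band
        resid = (patient.gfa - scaffold.mu) / scaffold.sigma
        vals = resid[patient.present]
        assert abs(np.nanmean(vals)) < 0.15

    def test_true_loads_recomputable_from_ground_truth(self):
        cfg, scaffold, rng = self._setup()
        planted = scaffold.nodes["label"].iloc[5:9].tolist()
        patient, effect, truth = generate_patient(cfg, scaffold, planted, rng)
        labels = patient.labels
        index = {l: i for i, l in enumerate(labels)}
        k = patient.present.sum(axis=1)
        a = np.zeros(len(labels))
        for aa, bb in truth.planted_edges:
            if (aa, bb) in effect.affected:
                continue
            a[index[aa]] += 1
            a[index[bb]] += 1
        recomputed = int(((k > 0) & (a / np.maximum(k, 1) >= 0.10)).sum())
        assert recomputed == truth.true_spared_load


class TestOutcomes:
    def _truths(self, loads):
        from sparenet import GroundTruth

        return [GroundTruth(patient_id=f"p{i}", planted_nodes=[], planted_edges=set(),
                            affected_edges=set(), true_pre_load=l, true_spared_load=l)
                for i, l in enumerate(loads)]

    def test_huge_slope_is_deterministic_in_load(self):
        cfg = GeneratorConfig(
            n_patients=20, seed=5,
            outcome_coefs=OutcomeCoefs(intercept=-400.0, spared_load=100.0,
                                       clinical={}, cutpoints=(0.2, 1.4, 2.6, 3.8)))
        rng = np.random.default_rng(0)
        clinical = generate_clinical(cfg, rng, ["left"] * 20)
        loads = [0, 0, 0, 0, 0, 8, 8, 8, 8, 8] * 2
        out = assign_outcomes(self._truths(loads), clinical, cfg,
                              rng=np.random.default_rng(1))
        assert (out.loc[np.array(loads) == 0, "ilae_year1"] == 1).all()
        assert (out.loc[np.array(loads) == 8, "ilae_year1"] == 5).all()

    def test_zero_slope_matches_interceptonly_expectation(self):
        coefs = OutcomeCoefs(intercept=0.0, spared_load=0.0, clinical={},
                             cutpoints=(0.0, 1.0, 2.0, 3.0))
        cfg = GeneratorConfig(n_patients=400, seed=5, outcome_coefs=coefs)
        rng = np.random.default_rng(0)
        clinical = generate_clinical(cfg, rng, ["left"] * 400)
        out = assign_outcomes(self._truths([3] * 400), clinical, cfg,
                              rng=np.random.default_rng(2))
        p_ilae1 = expit(0.0)  # P(logistic noise <= first cutpoint - 0)
        frac = (out["ilae_year1"] == 1).mean()
        se = np.sqrt(p_ilae1 * (1 - p_ilae1) / 400)
        assert abs(frac - p_ilae1) < 4 * se

    def test_relapse_only_for_ilae_1_2(self, small_cohort):
        out = small_cohort.outcomes
        bad = out["ilae_year1"] >= 3
        relapse_cols = [c for c in out.columns if c.startswith("relapse_year")]
        assert out.loc[bad, relapse_cols].isna().all().all()

    def test_censoring_truncates_labels(self, small_cohort):
        out = small_cohort.outcomes
        short = out[(out["followup_years"] == 2) & (out["ilae_year1"] <= 2)]
        no_relapse_yet = short[short["relapse_year2"] == 0]
        assert no_relapse_yet["relapse_year5"].isna().all()

    def test_mismatched_lengths_error(self):
        cfg = GeneratorConfig(n_patients=3, seed=1)
        clinical = generate_clinical(cfg, np.random.default_rng(0), ["left"] * 3)
        with pytest.raises(ConfigError):
            assign_outcomes(self._truths([1]), clinical, cfg)
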