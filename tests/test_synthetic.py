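"""The cohort generator: determinism, construction rules, designed effects."""

import numpy as np
import pandas as pd
import pytest

from dynstates.synthetic import (
    GeneratorConfig,
    GroupEffect,
    generate_cohort,
    make_generating_model,
    sample_observations,
    sample_state_path,
    validate_clinical_table,
    write_fixture,
)
from dynstates.parcellation import SubjectTimeSeries


class TestGeneratingModel:
    def test_seeded_determinism(self):
        cfg = GeneratorConfig(seed=7)
        t1 = make_generating_model(cfg)
        t2 = make_generating_model(cfg)
        assert np.array_equal(t1.true_state_means, t2.true_state_means)
        for g in ("patient", "control"):
            assert np.array_equal(
                t1.true_transition_matrices[g], t2.true_transition_matrices[g]
            )
        assert np.array_equal(t1.true_state_covariances, t2.true_state_covariances)

    def test_zero_separation_collapses_means(self):
        truth = make_generating_model(GeneratorConfig(mean_separation=0.0, seed=1))
        assert np.allclose(truth.true_state_means, 0.0)

    def test_sticky_uniform_construction(self):
        truth = make_generating_model(
            GeneratorConfig(transition_stickiness=0.9, group_effect=None, seed=0)
        )
        for a in truth.true_transition_matrices.values():
            assert np.allclose(np.diag(a), 0.9)
            off = a[~np.eye(6, dtype=bool)]
            assert np.allclose(off, 0.02)

    def test_rows_stochastic_and_covariances_spd(self):
        truth = make_generating_model(GeneratorConfig(seed=3))
        for a in truth.true_transition_matrices.values():
            assert np.allclose(a.sum(axis=1), 1.0, atol=1e-12)
        assert np.isclose(truth.true_initial_distribution.sum(), 1.0, atol=1e-12)
        for cov in truth.true_state_covariances:
            assert np.allclose(cov, cov.T)
            assert np.linalg.eigvalsh(cov).min() > 0

    def test_group_effect_confined_to_named_rows(self):
        """Only rows touched by the group effect differ between groups."""
        eff = GroupEffect()
        truth = make_generating_model(GeneratorConfig(seed=2, group_effect=eff))
        pat = truth.true_transition_matrices["patient"]
        con = truth.true_transition_matrices["control"]
        touched = {eff.fo_up_state, eff.fo_down_state, eff.transition_from}
        for row in range(6):
            if row in touched:
                assert not np.allclose(pat[row], con[row])
            else:
                assert np.allclose(pat[row], con[row], atol=1e-12)

    def test_null_state_occupancy_preserved(self):
        """Non-designated states keep control-level stationary occupancy."""
        truth = make_generating_model(GeneratorConfig(seed=5))
        pp = truth.stationary_distribution("patient")
        pc = truth.stationary_distribution("control")
        eff = truth.config.group_effect
        for s in range(6):
            if s in (eff.fo_up_state, eff.fo_down_state):
                assert abs(pp[s] - pc[s]) > 0.05
            else:
                assert abs(pp[s] - pc[s]) < 1e-8

    def test_invalid_effect_index_rejected(self):
        with pytest.raises(ValueError, match="state index"):
            GeneratorConfig(group_effect=GroupEffect(fo_up_state=9)).validate()


class TestStatePaths:
    def test_identity_dynamics_freeze_path(self):
        truth = make_generating_model(GeneratorConfig(seed=1, group_effect=None))
        truth.true_transition_matrices["control"] = np.eye(6)
        path = sample_state_path(truth, "control", 50, seed=0)
        assert np.all(path == path[0])

    def test_stationary_frequencies_on_long_path(self):
        truth = make_generating_model(GeneratorConfig(seed=4, group_effect=None))
        path = sample_state_path(truth, "control", 10_000, seed=11)
        freq = np.bincount(path, minlength=6) / path.size
        target = truth.stationary_distribution("control")
        assert np.max(np.abs(freq - target)) < 0.02

    def test_bad_length_rejected(self):
        truth = make_generating_model(GeneratorConfig(seed=1))
        with pytest.raises(ValueError):
            sample_state_path(truth, "control", 0, seed=0)


class TestObservations:
    def test_vanishing_noise_recovers_state_means(self):
        cfg = GeneratorConfig(noise_scale=1e-7, n_regions=6, seed=2)
        truth = make_generating_model(cfg)
        path = np.array([0, 1, 2, 3, 4, 5, 0, 1])
        ts = sample_observations(truth, path, seed=3)
        assert np.max(np.abs(ts.data - truth.true_state_means[path])) < 1e-6

    def test_seeded_repeatability(self):
        truth = make_generating_model(GeneratorConfig(seed=2))
        path = sample_state_path(truth, "patient", 100, seed=5)
        a = sample_observations(truth, path, seed=6)
        b = sample_observations(truth, path, seed=6)
        assert np.array_equal(a.data, b.data)

    def test_sample_covariance_converges(self):
        """Long constant path: sample covariance approaches the state's."""
        cfg = GeneratorConfig(n_regions=6, seed=8)
        truth = make_generating_model(cfg)
        path = np.zeros(5000, dtype=int)
        ts = sample_observations(truth, path, seed=9)
        sample_cov = np.cov(ts.data.T)
        true_cov = truth.true_state_covariances[0]
        rel = np.linalg.norm(sample_cov - true_cov) / np.linalg.norm(true_cov)
        assert rel < 0.10


class TestCohort:
    def test_default_emulation_dimensions(self):
        subjects, clinical, truth = generate_cohort(GeneratorConfig(seed=0))
        assert len(subjects) == 66
        assert all(s.data.shape == (190, 20) for s in subjects)
        assert (clinical.group == "patient").sum() == 35
        assert (clinical.group == "control").sum() == 31
        validate_clinical_table(clinical)

    def test_bitwise_reproducible(self):
        s1, c1, t1 = generate_cohort(GeneratorConfig(seed=13))
        s2, c2, t2 = generate_cohort(GeneratorConfig(seed=13))
        assert all(np.array_equal(a.data, b.data) for a, b in zip(s1, s2))
        pd.testing.assert_frame_equal(c1, c2)
        for sid in t1.true_state_paths:
            assert np.array_equal(t1.true_state_paths[sid], t2.true_state_paths[sid])

    def test_no_clinical_effect_gives_null_correlation(self):
        from dynstates.stats import spearman

        cfg = GeneratorConfig(clinical_effect=0.0, seed=21)
        subjects, clinical, truth = generate_cohort(cfg)
        eff = cfg.group_effect
        pats = clinical[clinical.group == "patient"]
        fo = np.array(
            [np.mean(truth.true_state_paths[sid] == eff.fo_up_state)
             for sid in pats.subject_id]
        )
        rho, _, _ = spearman(fo, pats.ibs_sss.to_numpy())
        assert abs(rho) < 0.25

    def test_strong_clinical_effect_gives_high_correlation(self):
        from dynstates.stats import spearman

        cfg = GeneratorConfig(clinical_effect=8.0, seed=22)
        subjects, clinical, truth = generate_cohort(cfg)
        eff = cfg.group_effect
        pats = clinical[clinical.group == "patient"]
        fo = np.array(
            [np.mean(truth.true_state_paths[sid] == eff.fo_up_state)
             for sid in pats.subject_id]
        )
        rho, _, _ = spearman(fo, pats.ibs_sss.to_numpy())
        assert rho > 0.8

    def test_mean_fo_converges_to_stationary(self):
        """Averaged over many subjects, empirical FO matches the chain's stationary law."""
        cfg = GeneratorConfig(
            n_regions=4, n_subjects_per_group=(40, 40), seed=17
        )
        subjects, clinical, truth = generate_cohort(cfg)
        for group in ("patient", "control"):
            ids = clinical.loc[clinical.group == group, "subject_id"]
            fo = np.mean(
                [np.bincount(truth.true_state_paths[sid], minlength=6) / 190
                 for sid in ids],
                axis=0,
            )
            assert np.max(np.abs(fo - truth.stationary_distribution(group))) < 0.03


def test_fixture_roundtrip(tmp_path):
    cfg = GeneratorConfig(n_regions=5, n_subjects_per_group=(2, 2),
                          n_timepoints=40, seed=3)
    subjects, clinical, truth = generate_cohort(cfg)
    out = write_fixture(tmp_path / "fx", subjects, clinical, truth)
    again = SubjectTimeSeries.from_tsv(
        out / "timeseries" / f"{subjects[0].subject_id}.tsv"
    )
    assert np.allclose(again.data, subjects[0].data, atol=1e-9)
    assert again.region_labels == subjects[0].region_labels
    table = pd.read_csv(out / "subjects.tsv", sep="\t")
    assert list(table.subject_id) == list(clinical.subject_id)
    assert (out / "ground_truth.json").exists()
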