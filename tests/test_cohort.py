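"""Synthetic cohort generator: distributional correctness, determinism,
clinical-score coupling and file round-trips."""

import numpy as np
import pytest

import fcgnn
from fcgnn.cohort import CovarianceError, _repair_pd


def test_same_seed_bitwise_identical():
    spec = fcgnn.CohortSpec(n_per_group=4, n_regions=12, series_length=60, seed=7)
    s1, m1 = fcgnn.generate_cohort(spec)
    s2, m2 = fcgnn.generate_cohort(spec)
    for a, b in zip(m1, m2):
        assert np.array_equal(a.values, b.values)
    assert [s.subject_id for s in s1] == [s.subject_id for s in s2]
    assert [s.age for s in s1] == [s.age for s in s2]


def test_matrices_well_formed(small_cohort):
    _, subjects, matrices = small_cohort
    assert len(subjects) == len(matrices) == 40
    for m in matrices:
        v = m.values
        assert np.array_equal(v, v.T)
        assert np.all(np.diag(v) == 0)
        assert np.all(np.isfinite(v))


def test_null_case_no_group_difference():
    """Without planted effects, patient and control edge means agree
    within sampling error (5 standard errors of the mean difference)."""
    spec = fcgnn.CohortSpec(n_per_group=40, n_regions=15, series_length=150, seed=3)
    subjects, matrices = fcgnn.generate_cohort(spec)
    V = np.stack([m.values for m in matrices])
    groups = np.array([s.group == "patient" for s in subjects])
    diff = V[groups].mean(axis=0) - V[~groups].mean(axis=0)
    se = np.sqrt(2.0 / 40) / np.sqrt(spec.series_length - 3)
    off = ~np.eye(15, dtype=bool)
    assert np.abs(diff[off]).max() < 5 * se


def test_planted_delta_matches_analytic_fisher_shift():
    """Monte Carlo group mean difference on the planted edge approaches the
    arctanh difference of the analytic (PD-repaired) correlations."""
    eff = fcgnn.PlantedEffect(4, 27, 0.3)
    spec = fcgnn.CohortSpec(n_per_group=1000, n_regions=30, series_length=500,
                            planted_effects=(eff,), seed=11)
    expected = (np.arctanh(spec.expected_correlation("patient")[4, 27])
                - np.arctanh(spec.expected_correlation("control")[4, 27]))
    subjects, matrices = fcgnn.generate_cohort(spec)
    V = np.stack([m.values for m in matrices])
    groups = np.array([s.group == "patient" for s in subjects])
    observed = V[groups, 4, 27].mean() - V[~groups, 4, 27].mean()
    se = np.sqrt(2.0 / 1000) / np.sqrt(497)
    assert abs(observed - expected) < 5 * se
    assert expected > 0.25  # the shift is a real, sizeable effect


def test_edgewise_mean_converges_to_block_fisher_z():
    """Control-group edgewise means converge to the Fisher-z of the
    specified block correlations (tolerance 0.05)."""
    spec = fcgnn.CohortSpec(n_per_group=500, n_regions=100, series_length=500,
                            seed=19)
    subjects, matrices = fcgnn.generate_cohort(spec)
    controls = np.stack([m.values for s, m in zip(subjects, matrices)
                         if s.group == "control"])
    mean_z = controls.mean(axis=0)
    target_r = spec.expected_correlation("control")
    np.fill_diagonal(target_r, 0.0)
    target = np.arctanh(target_r)
    assert np.abs(mean_z - target).max() < 0.05


def test_spec_validation():
    with pytest.raises(ValueError, match="positive"):
        fcgnn.CohortSpec(n_per_group=0)
    with pytest.raises(ValueError, match="out of range"):
        fcgnn.CohortSpec(n_regions=10, planted_effects=(fcgnn.PlantedEffect(0, 99, 0.1),))
    with pytest.raises(ValueError, match="diagonal"):
        fcgnn.CohortSpec(n_regions=10, planted_effects=(fcgnn.PlantedEffect(3, 3, 0.1),))
    with pytest.raises(ValueError, match=">= 1"):
        fcgnn.CohortSpec(n_regions=10, base_between=0.8,
                         network_assignment=tuple("AB" * 5),
                         planted_effects=(fcgnn.PlantedEffect(0, 1, 0.3),))


def test_pd_repair_restores_unit_diagonal_and_positive_definiteness():
    # a correlation matrix broken by an extreme planted shift
    C = np.full((4, 4), 0.1)
    np.fill_diagonal(C, 1.0)
    C[0, 1] = C[1, 0] = 0.95
    C[0, 2] = C[2, 0] = 0.95
    C[1, 2] = C[2, 1] = -0.9     # jointly infeasible -> not PD
    assert np.linalg.eigvalsh(C).min() < 0
    R = _repair_pd(C)
    assert np.linalg.eigvalsh(R).min() > 0
    assert np.allclose(np.diag(R), 1.0)


def test_matched_demographics():
    spec = fcgnn.CohortSpec(n_per_group=10, n_regions=8, series_length=50, seed=5)
    subjects, _ = fcgnn.generate_cohort(spec)
    controls = [s for s in subjects if s.group == "control"]
    patients = [s for s in subjects if s.group == "patient"]
    for c, p in zip(controls, patients):
        assert c.sex == p.sex and c.site == p.site
        assert abs(c.age - p.age) <= 2.0


class TestClinicalScores:
    def _cohort(self, seed=21):
        spec = fcgnn.CohortSpec(n_per_group=50, n_regions=10, series_length=150,
                                seed=seed)
        return spec, *fcgnn.generate_cohort(spec)

    def test_noise_free_coupling_is_perfectly_correlated(self):
        _, subjects, matrices = self._cohort()
        c = fcgnn.ClinicalCoupling(1, 7, slope=30.0, intercept=10.0, noise_sd=0.0)
        fcgnn.generate_clinical_scores(subjects, matrices, {"scale": c}, seed=0)
        fc = np.array([m.values[1, 7] for m in matrices])
        sc = np.array([s.clinical_scores["scale"] for s in subjects])
        assert abs(np.corrcoef(fc, sc)[0, 1] - 1.0) < 1e-12

    def test_zero_slope_gives_null_correlation(self):
        _, subjects, matrices = self._cohort()
        c = fcgnn.ClinicalCoupling(1, 7, slope=0.0, noise_sd=5.0)
        fcgnn.generate_clinical_scores(subjects, matrices, {"scale": c}, seed=1)
        fc = np.array([m.values[1, 7] for m in matrices])
        sc = np.array([s.clinical_scores["scale"] for s in subjects])
        from scipy import stats
        r, p = stats.pearsonr(fc, sc)
        assert abs(r) < 0.3 and p * 60 > 0.05  # not Bonferroni-significant

    def test_missing_edge_rejected(self):
        _, subjects, matrices = self._cohort()
        with pytest.raises(ValueError, match="missing edge"):
            fcgnn.generate_clinical_scores(
                subjects, matrices, {"x": fcgnn.ClinicalCoupling(1, 99, 1.0)}, seed=0)

    def test_missingness_representable(self):
        _, subjects, matrices = self._cohort()
        c = fcgnn.ClinicalCoupling(0, 3, slope=1.0)
        fcgnn.generate_clinical_scores(subjects, matrices, {"s": c}, seed=2,
                                       missing_rate=0.3)
        missing = sum(s.clinical_scores["s"] is None for s in subjects)
        assert 0 < missing < len(subjects)

    def test_target_r_coupling_recovers_in_one_replicate(self):
        spec, subjects, matrices = self._cohort(seed=33)
        c = fcgnn.coupling_for_target_r(spec, 2, 8, r=0.5)
        fcgnn.generate_clinical_scores(subjects, matrices, {"s": c}, seed=3)
        fc = np.array([m.values[2, 8] for m in matrices])
        sc = np.array([s.clinical_scores["s"] for s in subjects])
        r = np.corrcoef(fc, sc)[0, 1]
        assert 0.2 < r < 0.75  # generous one-shot band around 0.5 at n=100


def test_cohort_round_trip_exact(tmp_path, small_cohort):
    spec, subjects, matrices = small_cohort
    c = fcgnn.ClinicalCoupling(2, 11, slope=20.0, noise_sd=1.0)
    fcgnn.generate_clinical_scores(subjects, matrices, {"score": c}, seed=4,
                                   missing_rate=0.2)
    fcgnn.write_cohort(subjects, matrices, tmp_path)
    subjects2, matrices2 = fcgnn.read_cohort(tmp_path)
    for a, b in zip(matrices, matrices2):
        assert np.array_equal(a.values, b.values)
    for sa, sb in zip(subjects, subjects2):
        assert sa.subject_id == sb.subject_id and sa.group == sb.group
        assert sa.age == sb.age and sa.sex == sb.sex and sa.site == sb.site
        assert sa.clinical_scores == sb.clinical_scores
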