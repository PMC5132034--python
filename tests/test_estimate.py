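import numpy as np
import pandas as pd
import pytest

from lmecomposite import (
    LongitudinalData,
    MLMEParams,
    TrialDesign,
    bivariate_params,
    estimate_weights_from_pilot,
    lme_weights,
    rescale_by_baseline_sd,
    simulate_trial,
    subject_ols,
    summary_measures_estimate,
    utd_weights,
    validate_params,
    weights_from_fit,
)
from lmecomposite.estimate import _fit_arrays


def data_from_array(y, times, test_names):
    n, p, m = y.shape
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n), p * m),
            "time": np.tile(np.repeat(times, m), n),
            "test": np.tile(list(test_names), n * p),
            "score": y.reshape(-1),
        }
    )
    return LongitudinalData(df, np.asarray(times, float), tuple(test_names), n)


class TestSubjectOLS:
    def test_exact_line_recovered(self, annual_3yr):
        t = annual_3yr.times
        y = (2.0 + 3.0 * t)[None, :, None]
        data = data_from_array(y, t, ("a",))
        inter, slopes, resid = subject_ols(data, annual_3yr)
        assert inter[0, 0] == pytest.approx(2.0)
        assert slopes[0, 0] == pytest.approx(3.0)
        assert np.allclose(resid, 0.0)

    def test_constant_shift_changes_intercept_only(self, annual_3yr):
        t = annual_3yr.times
        rng = np.random.default_rng(0)
        y = rng.standard_normal((4, 4, 1))
        i0, s0, r0 = subject_ols(data_from_array(y, t, ("a",)), annual_3yr)
        i1, s1, r1 = subject_ols(data_from_array(y + 5.0, t, ("a",)), annual_3yr)
        assert np.allclose(i1, i0 + 5.0)
        assert np.allclose(s1, s0)
        assert np.allclose(r1, r0)

    def test_closed_form_slope_on_worked_example(self, annual_3yr):
        t = annual_3yr.times
        y = np.array([1.0, 2.0, 2.0, 4.0])[None, :, None]
        _, slopes, _ = subject_ols(data_from_array(y, t, ("a",)), annual_3yr)
        # slope = sum((t - 1.5) * y) / 5 = 0.9
        assert slopes[0, 0] == pytest.approx(0.9)

    def test_residuals_orthogonal_to_design(self, annual_3yr):
        t = annual_3yr.times
        y = np.random.default_rng(1).standard_normal((6, 4, 2))
        _, _, resid = subject_ols(data_from_array(y, t, ("a", "b")), annual_3yr)
        assert np.allclose(resid.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(np.einsum("k,nkm->nm", t, resid), 0.0, atol=1e-12)

    def test_two_visit_design_rejected(self):
        d = TrialDesign(np.array([0.0, 1.0]))
        y = np.zeros((2, 2, 1))
        with pytest.raises(ValueError, match="too short"):
            subject_ols(data_from_array(y, d.times, ("a",)), d)


class TestRescaleByBaselineSD:
    def test_unit_sd_scores_unchanged(self, annual_3yr):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((500, 4, 1))
        y[:, 0, 0] /= y[:, 0, 0].std(ddof=1)  # force baseline SD exactly 1
        data = data_from_array(y, annual_3yr.times, ("a",))
        rescaled, sds = rescale_by_baseline_sd(data)
        assert sds[0] == pytest.approx(1.0)
        assert np.allclose(rescaled.to_array(), y)

    def test_constant_baseline_rejected(self, annual_3yr):
        y = np.ones((5, 4, 1))
        data = data_from_array(y, annual_3yr.times, ("a",))
        with pytest.raises(ValueError, match="zero baseline standard deviation"):
            rescale_by_baseline_sd(data)

    def test_recovers_known_scale(self, annual_3yr):
        p = validate_params(
            MLMEParams(
                beta=np.array([1.0]),
                sigma_b=np.eye(1),
                sigma_e=np.eye(1),
                sigma_a=np.array([[9.0]]),  # baseline var 9 + 1 => SD sqrt(10)
            )
        )
        data = simulate_trial(p, annual_3yr, 20_000, seed=3)
        _, sds = rescale_by_baseline_sd(data)
        assert sds[0] == pytest.approx(np.sqrt(10.0), rel=0.03)


class TestSummaryMeasures:
    def test_noiseless_data_attributes_variance_to_slopes(self, annual_3yr):
        p = validate_params(
            MLMEParams(
                beta=np.array([1.0, 1.0]),
                sigma_b=np.array([[0.5, 0.2], [0.2, 2.0]]),
                sigma_e=1e-12 * np.eye(2),
            )
        )
        data = simulate_trial(p, annual_3yr, 2_000, seed=4)
        fit = summary_measures_estimate(data, annual_3yr)
        assert np.abs(fit.sigma_e_hat).max() < 1e-10
        assert np.allclose(fit.sigma_b_hat, fit.slope_cov_hat, atol=1e-10)

    def test_parameter_recovery_at_large_n(self, annual_3yr):
        p = bivariate_params(0.5)
        data = simulate_trial(p, annual_3yr, 100_000, seed=5)
        fit = summary_measures_estimate(data, annual_3yr)
        assert np.allclose(fit.beta_hat, p.beta, rtol=0.02)
        assert np.abs(fit.sigma_e_hat - p.sigma_e).max() / np.abs(p.sigma_e).max() < 0.02
        assert np.abs(fit.sigma_b_hat - p.sigma_b).max() / np.abs(p.sigma_b).max() < 0.02
        assert not fit.psd_adjusted

    def test_residual_divisor_unbiased(self, annual_3yr):
        """E[sum r^2] = (p-2) sigma_e_jj per subject at p = 4."""
        p = bivariate_params(0.2)
        rng = np.random.default_rng(6)
        diags = []
        for _ in range(200):
            y = rng.standard_normal((50, 4, 1)) * np.sqrt(2.0)  # pure noise, var 2
            fit = _fit_arrays(y, annual_3yr)
            diags.append(fit.sigma_e_hat[0, 0])
        assert np.mean(diags) == pytest.approx(2.0, rel=0.02)

    def test_dataframe_and_array_paths_identical(self, annual_3yr):
        p = bivariate_params(0.2)
        data = simulate_trial(p, annual_3yr, 50, seed=8)
        fit_df = summary_measures_estimate(data, annual_3yr)
        fit_arr = _fit_arrays(data.to_array(), annual_3yr)
        assert np.array_equal(fit_df.beta_hat, fit_arr.beta_hat)
        assert np.array_equal(fit_df.sigma_e_hat, fit_arr.sigma_e_hat)
        assert np.array_equal(fit_df.sigma_b_hat, fit_arr.sigma_b_hat)

    def test_psd_clip_flagged_and_repairs(self, annual_3yr):
        # tiny n with huge residual noise makes sigma_b_hat indefinite often
        p = validate_params(
            MLMEParams(
                beta=np.array([1.0, 1.0]),
                sigma_b=1e-4 * np.eye(2),
                sigma_e=np.array([[4.0, 0.0], [0.0, 4.0]]),
            )
        )
        flagged = 0
        for seed in range(20):
            data = simulate_trial(p, annual_3yr, 5, seed=seed)
            fit = summary_measures_estimate(data, annual_3yr)
            if fit.psd_adjusted:
                flagged += 1
            assert np.linalg.eigvalsh(fit.sigma_b_hat)[0] >= -1e-12
        assert flagged > 0

    def test_too_few_subjects_rejected(self, annual_3yr):
        y = np.zeros((1, 4, 2))
        with pytest.raises(ValueError, match="at least 2 subjects"):
            _fit_arrays(y, annual_3yr)


class TestEstimatedWeights:
    def test_consistency_toward_true_weights(self, annual_3yr):
        p = bivariate_params(0.2)
        data = simulate_trial(p, annual_3yr, 100_000, seed=10)
        cw = estimate_weights_from_pilot(data, annual_3yr, annual_3yr)
        np.testing.assert_allclose(cw.w, lme_weights(p, annual_3yr).w, atol=0.01)

    def test_pilot_informs_different_trial_design(self, annual_3yr):
        """Estimates from a 4-visit pilot weighted for a t=[0,1] trial equal UTD."""
        p = bivariate_params(0.5)
        data = simulate_trial(p, annual_3yr, 500, seed=11)
        fit = summary_measures_estimate(data, annual_3yr)
        trial = TrialDesign(np.array([0.0, 1.0]))
        cw = weights_from_fit(fit, trial)
        est_params = validate_params(
            MLMEParams(
                beta=fit.beta_hat,
                sigma_b=fit.sigma_b_hat + 1e-12 * np.eye(2),
                sigma_e=fit.sigma_e_hat,
            )
        )
        np.testing.assert_allclose(cw.w, utd_weights(est_params).w, rtol=1e-8)

    def test_small_pilot_weights_are_normalized_with_positive_slope(self, annual_3yr):
        p = bivariate_params(0.8)
        for seed in range(10):
            data = simulate_trial(p, annual_3yr, 12, seed=seed)
            cw = estimate_weights_from_pilot(data, annual_3yr, annual_3yr)
            assert np.abs(cw.w).sum() == pytest.approx(1.0, abs=1e-12)
            fit = summary_measures_estimate(data, annual_3yr)
            assert cw.w @ fit.beta_hat >= 0
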