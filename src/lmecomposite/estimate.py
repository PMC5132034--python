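"""Summary-measures estimation of the mixed-model parameters from pilot data.

Method-of-moments estimation built from per-subject ordinary least squares
fits, requiring balanced complete data with at least three visits (with two
visits the slope covariance and the residual covariance cannot be separated):

* ``beta_hat``     — mean of the per-subject OLS slope vectors;
* ``sigma_e_hat``  — pooled residual cross-products divided by n(p - 2), the
  residual degrees of freedom shared across tests under balance;
* ``slope_cov_hat``— sample covariance of the subject slope vectors, which
  targets ``sigma_b + tau_e(t) sigma_e``;
* ``sigma_b_hat``  — moment subtraction ``slope_cov_hat - tau_e sigma_e_hat``,
  projected onto the positive semidefinite cone by clipping negative
  eigenvalues at zero (flagged when the projection binds).

Estimated weights for a planned trial then reuse the optimal-weight formula
with the estimates in place of the truth; the pilot and trial designs may
differ, which is what lets a short pilot inform a longer trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .design import TrialDesign, design_term
from .simulate import LongitudinalData
from .weights import CompositeWeights, _normalized

__all__ = [
    "SummaryMeasuresFit",
    "rescale_by_baseline_sd",
    "subject_ols",
    "summary_measures_estimate",
    "weights_from_fit",
    "estimate_weights_from_pilot",
]


@dataclass(frozen=True)
class SummaryMeasuresFit:
    """Moment estimates of (beta, sigma_e, sigma_b) from balanced pilot data."""

    beta_hat: np.ndarray
    sigma_e_hat: np.ndarray
    sigma_b_hat: np.ndarray
    slope_cov_hat: np.ndarray
    n_subjects: int
    design: TrialDesign
    test_names: tuple[str, ...] = ()
    psd_adjusted: bool = False

    def to_dict(self) -> dict:
        return {
            "test_names": list(self.test_names),
            "beta_hat": self.beta_hat.tolist(),
            "sigma_e_hat": self.sigma_e_hat.tolist(),
            "sigma_b_hat": self.sigma_b_hat.tolist(),
            "slope_cov_hat": self.slope_cov_hat.tolist(),
            "n_subjects": self.n_subjects,
            "design": self.design.to_dict(),
            "psd_adjusted": self.psd_adjusted,
        }


def rescale_by_baseline_sd(data: LongitudinalData) -> tuple[LongitudinalData, np.ndarray]:
    """Divide each test's scores by its baseline sample SD.

    Puts all tests on a common scale so the weights are interpretable;
    returns the SDs so weights can be mapped back to raw score units.
    """
    t0 = data.times[0]
    base = data.data[np.isclose(data.data["time"], t0)]
    sds = np.empty(len(data.test_names))
    for j, name in enumerate(data.test_names):
        scores = base.loc[base["test"] == name, "score"].to_numpy()
        if scores.shape[0] < 2:
            raise ValueError(f"need at least 2 baseline scores for test {name!r}")
        sds[j] = np.std(scores, ddof=1)
        if sds[j] == 0.0:
            raise ValueError(f"zero baseline standard deviation for test {name!r}")
    df = data.data.copy()
    scale = df["test"].map({n: s for n, s in zip(data.test_names, sds)})
    df["score"] = df["score"] / scale
    rescaled = LongitudinalData(
        data=df,
        times=data.times,
        test_names=data.test_names,
        n_subjects=data.n_subjects,
        seed=data.seed,
    )
    return rescaled, sds


def _ols_arrays(y: np.ndarray, times: np.ndarray):
    """Per-subject, per-test OLS on an (n, p, m) array.

    Returns (intercepts, slopes, residuals) of shapes (n, m), (n, m), (n, p, m).
    """
    tc = times - times.mean()
    sxx = float(tc @ tc)
    slopes = np.einsum("k,nkm->nm", tc, y) / sxx
    intercepts = y.mean(axis=1) - slopes * times.mean()
    fitted = intercepts[:, None, :] + slopes[:, None, :] * times[None, :, None]
    return intercepts, slopes, y - fitted


def subject_ols(data: LongitudinalData, design: TrialDesign):
    """Per-subject, per-test least-squares lines.

    Requires p >= 3 visits; with fewer the downstream moment decomposition is
    not identified.
    """
    if design.n_times < 3:
        raise ValueError("design too short to separate sigma_b from sigma_e (need p >= 3)")
    if not np.allclose(data.times, design.times, atol=1e-9):
        raise ValueError("data measurement times do not match the design")
    y = data.to_array()
    return _ols_arrays(y, design.times)


def _fit_arrays(y: np.ndarray, design: TrialDesign) -> SummaryMeasuresFit:
    """Summary-measures estimation on an (n, p, m) score array."""
    n, p, m = y.shape
    if p < 3:
        raise ValueError("design too short to separate sigma_b from sigma_e (need p >= 3)")
    if n < 2:
        raise ValueError("need at least 2 subjects to estimate covariances")
    _, slopes, resid = _ols_arrays(y, design.times)

    sigma_e_hat = np.einsum("nkj,nkl->jl", resid, resid) / (n * (p - 2))
    centered = slopes - slopes.mean(axis=0)
    slope_cov = centered.T @ centered / (n - 1)

    tau = design_term(design)
    sigma_b_raw = slope_cov - tau * sigma_e_hat
    eigval, eigvec = np.linalg.eigh(sigma_b_raw)
    adjusted = bool(eigval[0] < 0)
    sigma_b_hat = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T if adjusted else sigma_b_raw

    return SummaryMeasuresFit(
        beta_hat=slopes.mean(axis=0),
        sigma_e_hat=sigma_e_hat,
        sigma_b_hat=sigma_b_hat,
        slope_cov_hat=slope_cov,
        n_subjects=n,
        design=design,
        psd_adjusted=adjusted,
    )


def summary_measures_estimate(
    data: LongitudinalData, design: TrialDesign
) -> SummaryMeasuresFit:
    """Estimate (beta, sigma_e, sigma_b) from balanced pilot data."""
    if not np.allclose(data.times, design.times, atol=1e-9):
        raise ValueError("data measurement times do not match the design")
    fit = _fit_arrays(data.to_array(), design)
    return SummaryMeasuresFit(
        **{**fit.__dict__, "test_names": data.test_names}
    )


def weights_from_fit(fit: SummaryMeasuresFit, trial_design: TrialDesign) -> CompositeWeights:
    """Optimal weights for a planned trial from estimated parameters.

    ``Lambda_hat = sigma_b_hat + tau_e(trial) * sigma_e_hat`` must be positive
    definite (re-checked here; the PSD clip of sigma_b_hat makes this the
    binding condition).
    """
    tau = design_term(trial_design)
    lam = fit.sigma_b_hat + tau * fit.sigma_e_hat
    eig = np.linalg.eigvalsh(lam)
    if eig[0] <= 1e-12 * max(eig[-1], 0.0):
        raise ValueError(
            f"estimated Lambda is not positive definite (smallest eigenvalue {eig[0]:.3e})"
        )
    raw = cho_solve(cho_factor(lam, lower=True), fit.beta_hat)
    w, ambiguous = _normalized(raw, fit.beta_hat)
    return CompositeWeights(
        w=w,
        scheme="lme",
        test_names=fit.test_names,
        design_used=trial_design,
        slope_sign_ambiguous=ambiguous,
    )


def estimate_weights_from_pilot(
    data: LongitudinalData, pilot_design: TrialDesign, trial_design: TrialDesign
) -> CompositeWeights:
    """Estimate model parameters from pilot data, then weight for the trial.

    The pilot design only needs p >= 3 visits; the trial design is arbitrary
    (including two-visit change-from-baseline endpoints).
    """
    fit = summary_measures_estimate(data, pilot_design)
    return weights_from_fit(fit, trial_design)
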