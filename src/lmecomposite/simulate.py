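"""Balanced multivariate longitudinal data simulator.

Draws complete data from the multivariate linear mixed effects model: per
subject, jointly normal random intercepts and slopes ``(a_i, b_i)`` with the
assembled 2m x 2m covariance described below, plus residuals with
cross-test covariance ``sigma_e`` at each visit and a common cross-time
autocorrelation ``Gamma_e(t)`` shared by all tests.

The random-effects covariance is assembled as

    G = [[sigma_a, C], [C', sigma_b]],
    C[j, j'] = corr_ab[j, j'] * sqrt(sigma_a[j, j] * sigma_b[j', j']),

with defaults sigma_a = sigma_b and corr_ab = 0.5 * corr(sigma_b), i.e. each
test's intercept-slope correlation is 0.5 and cross-test intercept-slope
correlations are 0.5 times the corresponding slope correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TrialDesign, autocorr_matrix
from .params import MLMEParams, _ensure_validated

__all__ = ["LongitudinalData", "random_effects_covariance", "simulate_trial"]


@dataclass(frozen=True)
class LongitudinalData:
    """Balanced long-format longitudinal data.

    ``data`` has columns subject_id, time, test, score; every subject has a
    score for every test at every design time.
    """

    data: pd.DataFrame
    times: np.ndarray
    test_names: tuple[str, ...]
    n_subjects: int
    seed: int | None = None

    def to_array(self) -> np.ndarray:
        """Scores as an (n_subjects, n_times, n_tests) array."""
        wide = self.data.pivot_table(
            index="subject_id", columns=["time", "test"], values="score", sort=False
        )
        cols = pd.MultiIndex.from_product([self.times, self.test_names])
        wide = wide.reindex(columns=cols)
        if wide.isna().any().any():
            raise ValueError("incomplete data: some subject/time/test cells are missing")
        n = wide.shape[0]
        return wide.to_numpy().reshape(n, len(self.times), len(self.test_names))


def random_effects_covariance(params: MLMEParams) -> np.ndarray:
    """Assembled 2m x 2m covariance of (a_i, b_i); raises if not PD."""
    params = _ensure_validated(params)
    sd_a = np.sqrt(np.diag(params.sigma_a))
    sd_b = np.sqrt(np.diag(params.sigma_b))
    cross = params.corr_ab * np.outer(sd_a, sd_b)
    g = np.block([[params.sigma_a, cross], [cross.T, params.sigma_b]])
    eig = np.linalg.eigvalsh(g)
    if eig[0] <= 1e-12 * max(eig[-1], 0.0):
        raise ValueError(
            "assembled random-effects covariance is not positive definite "
            f"(smallest eigenvalue {eig[0]:.3e})"
        )
    return g


def _draw_scores(
    params: MLMEParams, design: TrialDesign, n_subjects: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an (n, p, m) score array from the model.  Core sampling path."""
    m = params.n_tests
    t = design.times
    g = random_effects_covariance(params)
    chol_g = np.linalg.cholesky(g)
    chol_e = np.linalg.cholesky(params.sigma_e)
    gamma = autocorr_matrix(design)

    re = rng.standard_normal((n_subjects, 2 * m)) @ chol_g.T
    intercepts = params.alpha + re[:, :m]
    slopes = params.beta + re[:, m:]

    # residuals with Cov(e_ikj, e_ik'j') = Gamma[k,k'] * sigma_e[j,j']
    z = rng.standard_normal((n_subjects, len(t), m))
    if design.autocorr.family != "identity":
        chol_gamma = np.linalg.cholesky(gamma)
        z = np.einsum("kl,nlm->nkm", chol_gamma, z)
    resid = z @ chol_e.T

    return intercepts[:, None, :] + slopes[:, None, :] * t[None, :, None] + resid


def simulate_trial(
    params: MLMEParams,
    design: TrialDesign,
    n_subjects: int,
    seed: int | np.random.Generator | None = None,
) -> LongitudinalData:
    """Simulate a balanced trial; reproducible for a fixed integer seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    params = _ensure_validated(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = _draw_scores(params, design, n_subjects, rng)

    n, p, m = y.shape
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(1, n + 1), p * m),
            "time": np.tile(np.repeat(design.times, m), n),
            "test": np.tile(list(params.test_names), n * p),
            "score": y.reshape(-1),
        }
    )
    return LongitudinalData(
        data=df,
        times=design.times.copy(),
        test_names=params.test_names,
        n_subjects=n,
        seed=seed if isinstance(seed, int) else None,
    )
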