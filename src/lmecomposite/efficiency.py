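"""Slope-estimator variance, sample-size ratios and percent-N reductions.

With balanced complete data, the variance of an efficient estimate of the
composite slope based on a single subject is the quadratic form
``w' Lambda_t w``, so the quantity

    N(w) = (w' Lambda_t w) / (w'beta)^2

is proportional to the sample size required to detect a nonzero composite
slope with given error rates.  Ratios of N between a composite and the best
single test (``N_composite / N_best``) are therefore relative sample-size
requirements: values below 1 mean the composite buys power, values above 1
mean it costs power.  At the optimal weights the composite attains
``N = 1 / (beta' Lambda_t^{-1} beta)``, the minimum over all w.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .design import TrialDesign, lambda_matrix
from .params import MLMEParams, _as_vector, _ensure_validated
from .weights import CompositeWeights, lme_weights

__all__ = [
    "EfficiencySummary",
    "slope_variance_unit",
    "n_proxy",
    "n_ratio",
    "best_test",
    "percent_n_reduction",
    "sample_size",
    "efficiency_summary",
    "duration_table",
]


def _weight_array(w, m: int) -> np.ndarray:
    if isinstance(w, CompositeWeights):
        w = w.w
    w = _as_vector(w, m, "w")
    if not np.any(w != 0.0):
        raise ValueError("weight vector must be nonzero")
    return w


def slope_variance_unit(params: MLMEParams, design: TrialDesign, w) -> float:
    """Per-subject composite slope estimator variance w' Lambda_t w."""
    params = _ensure_validated(params)
    w = _weight_array(w, params.n_tests)
    return float(w @ lambda_matrix(params, design) @ w)


def n_proxy(params: MLMEParams, design: TrialDesign, w) -> float:
    """Sample-size proxy N(w) = (w'Lambda w) / (w'beta)^2."""
    params = _ensure_validated(params)
    w = _weight_array(w, params.n_tests)
    slope = float(w @ params.beta)
    if slope == 0.0:
        raise ValueError("composite slope is zero; sample-size proxy undefined")
    return slope_variance_unit(params, design, w) / slope**2


def n_ratio(params: MLMEParams, design: TrialDesign, w, reference) -> float:
    """Relative sample size N(w) / N(v) against a reference direction.

    ``reference`` is either a test index (the composite is compared with
    using that single test alone) or a full weight vector.
    """
    params = _ensure_validated(params)
    if np.isscalar(reference):
        v = np.zeros(params.n_tests)
        v[int(reference)] = 1.0
    else:
        v = reference
    return n_proxy(params, design, w) / n_proxy(params, design, v)


def best_test(params: MLMEParams, design: TrialDesign) -> int:
    """Index of the most efficient single test: argmin_j Lambda_jj / beta_j^2.

    Tests with a zero slope are excluded.  Ties go to the lowest index.
    """
    params = _ensure_validated(params)
    lam = lambda_matrix(params, design)
    with np.errstate(divide="ignore"):
        per_test = np.where(
            params.beta != 0.0, np.diag(lam) / params.beta**2, np.inf
        )
    if not np.isfinite(per_test).any():
        raise ValueError("no test has a nonzero slope")
    best = int(np.argmin(per_test))
    if np.sum(np.isclose(per_test, per_test[best], rtol=1e-12)) > 1:
        warnings.warn("best-test tie; returning the lowest index", stacklevel=2)
    return best


def composite_min_n(params: MLMEParams, design: TrialDesign) -> float:
    """Minimum sample-size proxy over all weights: 1 / (beta' Lambda^{-1} beta)."""
    params = _ensure_validated(params)
    lam = lambda_matrix(params, design)
    return 1.0 / float(params.beta @ cho_solve(cho_factor(lam, lower=True), params.beta))


def percent_n_reduction(params: MLMEParams, design: TrialDesign) -> float:
    """Percent sample-size saving of the optimal composite over the best test."""
    params = _ensure_validated(params)
    if params.n_tests == 1:
        return 0.0
    best = best_test(params, design)
    ratio = n_ratio(params, design, lme_weights(params, design), best)
    return 100.0 * (1.0 - ratio)


def sample_size(
    params: MLMEParams,
    design: TrialDesign,
    w,
    effect_fraction: float = 1.0,
    alpha: float = 0.05,
    power: float = 0.8,
) -> int:
    """Per-arm sample size to detect a fractional slowing of the composite slope.

    Two-arm normal approximation
    ``n = 2 (z_{1-alpha/2} + z_{power})^2 * w'Lambda w / (k * w'beta)^2``,
    rounded up, where ``k`` is the treatment effect expressed as a fraction of
    the placebo composite slope.
    """
    if not 0 < effect_fraction <= 1:
        raise ValueError("effect_fraction must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0.5 < power < 1:
        raise ValueError("power must lie in (0.5, 1)")
    z = norm.ppf(1 - alpha / 2) + norm.ppf(power)
    n = 2.0 * z**2 * n_proxy(params, design, w) / effect_fraction**2
    return ceil(n)


@dataclass(frozen=True)
class EfficiencySummary:
    """Per-test and composite sample-size proxies for one design."""

    per_test_n: np.ndarray
    composite_n: float
    best_index: int
    ratio_composite_best: float
    pct_reduction: float
    test_names: tuple[str, ...] = ()
    weights: CompositeWeights | None = None

    def to_dict(self) -> dict:
        names = self.test_names or tuple(
            f"test{j+1}" for j in range(self.per_test_n.shape[0])
        )
        d = {
            "per_test_N": {n: float(v) for n, v in zip(names, self.per_test_n)},
            "composite_N": self.composite_n,
            "best_test": names[self.best_index],
            "N_composite_over_N_best": self.ratio_composite_best,
            "pct_N_reduction": self.pct_reduction,
        }
        if self.weights is not None:
            d["weights"] = self.weights.to_dict()
        return d


def efficiency_summary(
    params: MLMEParams, design: TrialDesign, w=None
) -> EfficiencySummary:
    """Summarize composite vs single-test efficiency for one trial design.

    ``w`` defaults to the design-optimal weights.
    """
    params = _ensure_validated(params)
    cw = lme_weights(params, design) if w is None else w
    lam = lambda_matrix(params, design)
    with np.errstate(divide="ignore"):
        per_test = np.where(params.beta != 0.0, np.diag(lam) / params.beta**2, np.inf)
    best = best_test(params, design)
    comp = n_proxy(params, design, cw)
    ratio = comp / per_test[best]
    return EfficiencySummary(
        per_test_n=per_test,
        composite_n=comp,
        best_index=best,
        ratio_composite_best=ratio,
        pct_reduction=100.0 * (1.0 - ratio),
        test_names=params.test_names,
        weights=cw if isinstance(cw, CompositeWeights) else None,
    )


def duration_table(params: MLMEParams, durations_months) -> "pd.DataFrame":
    """Optimal change-from-baseline weights and %N-reduction by trial duration.

    For each duration T (months) the endpoint is change from baseline to last
    observation, i.e. the two-visit design t = [0, T/12] years.
    """
    import pandas as pd

    rows = []
    for months in durations_months:
        design = TrialDesign.change_from_baseline(months / 12.0)
        cw = lme_weights(params, design)
        summ = efficiency_summary(params, design, cw)
        row = {"duration_months": months}
        row.update({f"w_{n}": v for n, v in zip(params.test_names, cw.w)})
        row["best_test"] = params.test_names[summ.best_index]
        row["pct_N_reduction"] = summ.pct_reduction
        rows.append(row)
    return pd.DataFrame(rows)
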