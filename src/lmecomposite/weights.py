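"""Composite weighting schemes.

The design-aware optimal weights maximize the squared composite slope
relative to the variance of its estimator,

    w* in argmax_{w != 0}  (w'beta)^2 / (w' Lambda_t w),

a generalized Rayleigh quotient whose maximizer is

    w_LME(t) = c * Lambda_t^{-1} beta,    Lambda_t = sigma_b + tau_e(t) sigma_e.

The constant c has no effect on efficiency; throughout we fix the convention
that the weights sum to 1 in absolute value and the composite slope w'beta is
positive.  Also provided: unit-time-decline (UTD) weights — the same formula
specialized to the two-visit unit-interval design t = [0, 1]; two-group
weights Lambda_t^{-1}(beta_trt - beta) for treatment/placebo contrasts when
proportional invariance cannot be assumed; and inverse-baseline-SD weights,
a common heuristic comparator.

Individual weights may oppose the sign of their own test's slope; such
"negative weights" exploit noise cancellation and are legitimate maximizers,
not errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .design import TrialDesign, lambda_matrix
from .params import MLMEParams, _as_vector, _ensure_validated

__all__ = [
    "CompositeWeights",
    "normalize",
    "lme_weights",
    "utd_weights",
    "two_group_weights",
    "inverse_sd_weights",
]


@dataclass(frozen=True)
class CompositeWeights:
    """A normalized weight vector with its provenance.

    ``sum_j |w_j| = 1`` and, for schemes that know ``beta``, the implied
    composite slope ``w'beta`` is positive.  ``slope_sign_ambiguous`` flags
    the degenerate user-supplied case ``w'beta = 0`` where no sign choice can
    make the slope positive.
    """

    w: np.ndarray
    scheme: str
    test_names: tuple[str, ...] = ()
    design_used: TrialDesign | None = None
    normalized: bool = True
    slope_sign_ambiguous: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))

    def to_dict(self) -> dict:
        names = self.test_names or tuple(f"test{j+1}" for j in range(self.w.shape[0]))
        d = {
            "scheme": self.scheme,
            "weights": {name: float(val) for name, val in zip(names, self.w)},
        }
        if self.design_used is not None:
            d["design"] = self.design_used.to_dict()
        return d


def _normalized(raw: np.ndarray, beta: np.ndarray | None) -> tuple[np.ndarray, bool]:
    total = np.abs(raw).sum()
    if total == 0.0:
        raise ValueError("weight vector must be nonzero")
    w = raw / total
    ambiguous = False
    if beta is not None:
        slope = w @ beta
        if slope < 0:
            w = -w
        elif slope == 0:
            ambiguous = True
    return w, ambiguous


def normalize(w, beta=None, scheme: str = "user", **kwargs) -> CompositeWeights:
    """Scale ``w`` so that sum |w_j| = 1, with positive composite slope.

    If ``beta`` is given the sign is flipped when ``w'beta < 0``; an exactly
    zero slope keeps the input sign and sets ``slope_sign_ambiguous``.
    """
    w = np.asarray(w, dtype=float)
    if beta is not None:
        beta = _as_vector(beta, w.shape[0], "beta")
    w, ambiguous = _normalized(w, beta)
    return CompositeWeights(w=w, scheme=scheme, slope_sign_ambiguous=ambiguous, **kwargs)


def _solve_spd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cho_solve(cho_factor(a, lower=True), b)


def lme_weights(params: MLMEParams, design: TrialDesign) -> CompositeWeights:
    """Design-optimal weights w proportional to Lambda_t^{-1} beta."""
    params = _ensure_validated(params)
    raw = _solve_spd(lambda_matrix(params, design), params.beta)
    w, _ = _normalized(raw, params.beta)
    return CompositeWeights(
        w=w, scheme="lme", test_names=params.test_names, design_used=design
    )


def utd_weights(params: MLMEParams) -> CompositeWeights:
    """Unit-time-decline weights: the t = [0, 1] special case of lme_weights."""
    design = TrialDesign(np.array([0.0, 1.0]))
    cw = lme_weights(params, design)
    return CompositeWeights(
        w=cw.w, scheme="utd", test_names=params.test_names, design_used=design
    )


def two_group_weights(
    params: MLMEParams, beta_trt, design: TrialDesign
) -> CompositeWeights:
    """Optimal weights for a treatment-versus-placebo slope contrast.

    ``w proportional to Lambda_t^{-1}(beta_trt - beta)``; the sign convention
    makes the detected slowing ``w'(beta - beta_trt)`` positive.  Under
    proportional invariance, ``beta_trt = (1 - k) beta``, this reduces to the
    one-group weights for every effect fraction k.
    """
    params = _ensure_validated(params)
    beta_trt = _as_vector(beta_trt, params.n_tests, "beta_trt")
    contrast = beta_trt - params.beta
    if not np.any(contrast != 0.0):
        raise ValueError("zero treatment contrast: beta_trt equals beta")
    raw = _solve_spd(lambda_matrix(params, design), contrast)
    w, _ = _normalized(raw, -contrast)  # w'(beta - beta_trt) > 0
    return CompositeWeights(
        w=w, scheme="lme2", test_names=params.test_names, design_used=design
    )


def inverse_sd_weights(baseline_sds, beta) -> CompositeWeights:
    """Heuristic weights proportional to 1 / baseline SD.

    Each component carries the sign of its own slope so that every test
    contributes non-negatively to the composite slope.  Design-agnostic.
    """
    sds = np.asarray(baseline_sds, dtype=float)
    beta = _as_vector(beta, sds.shape[0], "beta")
    if np.any(sds <= 0):
        raise ValueError("baseline standard deviations must be positive")
    raw = np.where(beta >= 0, 1.0, -1.0) / sds
    w, _ = _normalized(raw, beta)
    return CompositeWeights(w=w, scheme="inverse_sd")
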