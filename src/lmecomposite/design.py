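"""Trial designs, residual autocorrelation and the scalar design term.

A planned trial is summarized by its measurement times ``t = [t_1..t_p]``
(years, strictly increasing, p >= 2) and a residual autocorrelation family.
For slope estimation the whole schedule collapses into a single scalar

    tau_e(t) = [ (X' Gamma^{-1} X)^{-1} ]_{22},   X = [1, t],

the residual contribution to the variance of an efficiently estimated
per-subject slope.  Without autocorrelation (Gamma = I) this reduces to
``1 / sum_k (t_k - tbar)^2``: spreading visits out or adding visits shrinks
tau_e.  The matrix

    Lambda_t = sigma_b + tau_e(t) * sigma_e

is the covariance of efficiently estimated per-subject slope vectors and is
the kernel of both the optimal weights and every sample-size ratio computed
in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .params import MLMEParams, _ensure_validated, check_positive_definite

__all__ = [
    "Autocorrelation",
    "TrialDesign",
    "autocorr_matrix",
    "design_term",
    "lambda_matrix",
]


@dataclass(frozen=True)
class Autocorrelation:
    """Residual autocorrelation family gamma(lag).

    ``identity`` gives gamma(lag) = 0 for lag > 0 (no autocorrelation);
    ``exponential`` gives gamma(lag) = exp(-rate * lag), rate > 0.  Both
    satisfy gamma(0) = 1 and yield positive definite correlation matrices for
    distinct times.
    """

    family: str = "identity"
    rate: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("identity", "exponential"):
            raise ValueError(f"unknown autocorrelation family {self.family!r}")
        if self.family == "exponential":
            if self.rate is None or not self.rate > 0:
                raise ValueError("exponential autocorrelation requires rate > 0")

    def __call__(self, lag: np.ndarray) -> np.ndarray:
        lag = np.asarray(lag, dtype=float)
        if self.family == "identity":
            return np.where(lag == 0.0, 1.0, 0.0)
        return np.exp(-self.rate * lag)

    def to_dict(self) -> dict:
        d = {"family": self.family}
        if self.rate is not None:
            d["rate"] = self.rate
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Autocorrelation":
        return cls(family=d.get("family", "identity"), rate=d.get("rate"))


@dataclass(frozen=True)
class TrialDesign:
    """Measurement schedule (years) plus residual autocorrelation family."""

    times: np.ndarray
    autocorr: Autocorrelation = Autocorrelation()

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        if t.ndim != 1 or t.shape[0] < 2:
            raise ValueError("a design needs at least two measurement times")
        if not np.all(np.diff(t) > 0):
            raise ValueError("measurement times must be strictly increasing (no duplicates)")
        object.__setattr__(self, "times", t)

    @property
    def n_times(self) -> int:
        return int(self.times.shape[0])

    @classmethod
    def equally_spaced(
        cls, duration: float, n_visits: int, autocorr: Autocorrelation | None = None
    ) -> "TrialDesign":
        """Visits at 0, d/(k-1), ..., d for a trial of ``duration`` years."""
        return cls(np.linspace(0.0, duration, n_visits), autocorr or Autocorrelation())

    @classmethod
    def change_from_baseline(
        cls, duration: float, autocorr: Autocorrelation | None = None
    ) -> "TrialDesign":
        """Two-visit design t = [0, T] for a baseline-to-last-visit endpoint."""
        return cls(np.array([0.0, duration]), autocorr or Autocorrelation())

    def to_dict(self) -> dict:
        return {"times": self.times.tolist(), "autocorr": self.autocorr.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "TrialDesign":
        return cls(
            np.asarray(d["times"], dtype=float),
            Autocorrelation.from_dict(d.get("autocorr", {})),
        )


def autocorr_matrix(design: TrialDesign) -> np.ndarray:
    """p x p residual autocorrelation matrix Gamma with entries gamma(|t_k - t_k'|)."""
    t = design.times
    gamma = design.autocorr(np.abs(t[:, None] - t[None, :]))
    check_positive_definite(gamma, "autocorrelation matrix")
    return gamma


def design_term(design: TrialDesign) -> float:
    """Scalar design term tau_e(t).

    Computed from the GLS information matrix ``X' Gamma^{-1} X`` with
    ``X = [1, t]``; for the identity family the closed form
    ``1 / sum (t_k - tbar)^2`` is evaluated as well and the two are required
    to agree, as an internal consistency check.
    """
    t = design.times
    gamma = autocorr_matrix(design)
    x = np.column_stack([np.ones_like(t), t])
    info = x.T @ cho_solve(cho_factor(gamma, lower=True), x)
    det = info[0, 0] * info[1, 1] - info[0, 1] ** 2
    if det <= 0:
        raise ValueError("singular design information matrix")
    tau = float(info[0, 0] / det)  # (2,2) entry of the 2x2 inverse
    if design.autocorr.family == "identity":
        closed = 1.0 / float(np.sum((t - t.mean()) ** 2))
        if not np.isclose(tau, closed, rtol=1e-12, atol=0.0):
            raise AssertionError("design term: matrix and closed-form paths disagree")
    return tau


def lambda_matrix(params: MLMEParams, design: TrialDesign) -> np.ndarray:
    """Slope covariance kernel Lambda_t = sigma_b + tau_e(t) sigma_e."""
    params = _ensure_validated(params)
    lam = params.sigma_b + design_term(design) * params.sigma_e
    check_positive_definite(lam, "Lambda_t")
    return lam
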