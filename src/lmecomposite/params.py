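"""Parameter containers for the multivariate linear mixed effects model.

The model for subject *i* observed on *m* outcome measures at time *t* is

    y_i(t) = alpha + a_i + (beta + b_i) t + e_i(t),

with jointly normal random intercepts ``a_i`` and slopes ``b_i`` and a
multivariate normal residual ``e_i(t)``.  Everything downstream — optimal
weights, efficiency ratios, the simulator — is driven by the fixed slope
vector ``beta``, the random-slope covariance ``sigma_b`` and the residual
covariance ``sigma_e``.  Intercept parameters do not affect composite
performance with balanced data and are used only by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MLMEParams",
    "CompositeMixedModel",
    "validate_params",
    "composite_model",
]

#: Relative tolerance for accepting a nearly symmetric matrix.
SYMMETRY_RTOL = 1e-8
#: A matrix is positive definite if min eig > PD_RTOL * max eig.
PD_RTOL = 1e-10


def _as_vector(x, m: int | None, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"conformability error: {name} must be a vector, got shape {v.shape}")
    if m is not None and v.shape[0] != m:
        raise ValueError(f"conformability error: {name} has length {v.shape[0]}, expected {m}")
    return v


def _as_symmetric(x, m: int, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (m, m):
        raise ValueError(f"conformability error: {name} has shape {a.shape}, expected ({m}, {m})")
    scale = max(1.0, float(np.abs(a).max()))
    if np.abs(a - a.T).max() > SYMMETRY_RTOL * scale:
        raise ValueError(f"{name} is not symmetric within tolerance")
    return 0.5 * (a + a.T)


def check_positive_definite(a: np.ndarray, name: str) -> None:
    """Raise ``ValueError`` unless ``a`` is strictly positive definite."""
    eig = np.linalg.eigvalsh(a)
    if eig[0] <= PD_RTOL * max(eig[-1], 0.0) or eig[-1] <= 0:
        raise ValueError(
            f"{name} is not positive definite (smallest eigenvalue {eig[0]:.3e})"
        )


@dataclass(frozen=True)
class MLMEParams:
    """Parameter set of the multivariate linear mixed effects model.

    Parameters
    ----------
    beta
        Fixed slope vector (score units per year); at least one entry nonzero.
    sigma_b
        ``m x m`` covariance of the random slopes, symmetric positive definite.
    sigma_e
        ``m x m`` residual covariance at a fixed time, symmetric positive
        definite.
    test_names
        Labels of the component measures; defaults to ``test1..testm``.
    alpha
        Fixed intercepts, default zero (irrelevant to composite efficiency
        under balance).
    sigma_a
        Random-intercept covariance; defaults to ``sigma_b``.
    corr_ab
        Intercept-slope correlations, ``corr_ab[j, j']`` linking ``a_ij`` to
        ``b_ij'``; defaults to ``0.5 * corr(sigma_b)`` so that each test's own
        intercept-slope correlation is 0.5 and cross-test correlations scale
        with the slope correlation.  Used only by the simulator.
    """

    beta: np.ndarray
    sigma_b: np.ndarray
    sigma_e: np.ndarray
    test_names: tuple[str, ...] = ()
    alpha: np.ndarray | None = None
    sigma_a: np.ndarray | None = None
    corr_ab: np.ndarray | None = None
    validated: bool = field(default=False, compare=False)

    @property
    def n_tests(self) -> int:
        return int(np.asarray(self.beta).shape[0])

    def to_dict(self) -> dict:
        d = {
            "test_names": list(self.test_names),
            "beta": np.asarray(self.beta).tolist(),
            "sigma_b": np.asarray(self.sigma_b).tolist(),
            "sigma_e": np.asarray(self.sigma_e).tolist(),
        }
        for key in ("alpha", "sigma_a", "corr_ab"):
            val = getattr(self, key)
            if val is not None:
                d[key] = np.asarray(val).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MLMEParams":
        return validate_params(
            cls(
                beta=np.asarray(d["beta"], dtype=float),
                sigma_b=np.asarray(d["sigma_b"], dtype=float),
                sigma_e=np.asarray(d["sigma_e"], dtype=float),
                test_names=tuple(d.get("test_names", ())),
                alpha=None if d.get("alpha") is None else np.asarray(d["alpha"], dtype=float),
                sigma_a=None if d.get("sigma_a") is None else np.asarray(d["sigma_a"], dtype=float),
                corr_ab=None if d.get("corr_ab") is None else np.asarray(d["corr_ab"], dtype=float),
            )
        )


def validate_params(params: MLMEParams) -> MLMEParams:
    """Validate and normalize an :class:`MLMEParams`.

    Symmetrizes the covariance matrices (within tolerance), fills in the
    defaults for the optional intercept structure and checks the model
    assumptions: strictly positive definite ``sigma_b`` and ``sigma_e`` and a
    nonzero ``beta``.
    """
    beta = _as_vector(params.beta, None, "beta")
    m = beta.shape[0]
    if m < 1:
        raise ValueError("conformability error: beta is empty")
    if not np.any(beta != 0.0):
        raise ValueError("beta must be nonzero")

    sigma_b = _as_symmetric(params.sigma_b, m, "sigma_b")
    sigma_e = _as_symmetric(params.sigma_e, m, "sigma_e")
    check_positive_definite(sigma_b, "sigma_b")
    check_positive_definite(sigma_e, "sigma_e")

    names = tuple(params.test_names) or tuple(f"test{j + 1}" for j in range(m))
    if len(names) != m:
        raise ValueError(f"conformability error: {len(names)} test names for {m} tests")

    alpha = np.zeros(m) if params.alpha is None else _as_vector(params.alpha, m, "alpha")
    sigma_a = sigma_b.copy() if params.sigma_a is None else _as_symmetric(params.sigma_a, m, "sigma_a")
    check_positive_definite(sigma_a, "sigma_a")
    if params.corr_ab is None:
        sd = np.sqrt(np.diag(sigma_b))
        corr_ab = 0.5 * sigma_b / np.outer(sd, sd)
    else:
        corr_ab = np.asarray(params.corr_ab, dtype=float)
        if corr_ab.shape != (m, m):
            raise ValueError(
                f"conformability error: corr_ab has shape {corr_ab.shape}, expected ({m}, {m})"
            )
    if np.abs(corr_ab).max() > 1.0 + 1e-12:
        raise ValueError("corr_ab entries must lie in [-1, 1]")

    return replace(
        params,
        beta=beta,
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        test_names=names,
        alpha=alpha,
        sigma_a=sigma_a,
        corr_ab=corr_ab,
        validated=True,
    )


def _ensure_validated(params: MLMEParams) -> MLMEParams:
    return params if params.validated else validate_params(params)


@dataclass(frozen=True)
class CompositeMixedModel:
    """Scalar mixed-model implied by a weighted composite z = w'y.

    ``mu = w'alpha`` and ``delta = w'beta`` are the fixed intercept and slope,
    ``var_d = w' sigma_b w`` the random-slope variance and
    ``var_r = w' sigma_e w`` the residual variance.
    """

    mu: float
    delta: float
    var_d: float
    var_r: float


def composite_model(params: MLMEParams, w) -> CompositeMixedModel:
    """Collapse the multivariate model onto the composite defined by ``w``."""
    params = _ensure_validated(params)
    w = _as_vector(w, params.n_tests, "w")
    if not np.any(w != 0.0):
        raise ValueError("weight vector must be nonzero")
    return CompositeMixedModel(
        mu=float(w @ params.alpha),
        delta=float(w @ params.beta),
        var_d=float(w @ params.sigma_b @ w),
        var_r=float(w @ params.sigma_e @ w),
    )
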