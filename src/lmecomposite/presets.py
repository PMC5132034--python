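"""Worked-example parameter sets.

``adcs_mci_params`` carries published multivariate mixed-model estimates for
three cognitive/functional instruments — the ADAS-Cog, the CDR Sum of Boxes
and the MMSE — fitted to the vitamin E arm (n = 257) of the ADCS
MCI/donepezil trial after dividing each test by its baseline standard
deviation.  ``bivariate_params`` is a stylized two-test configuration (one
efficient test, one inefficient, with adjustable slope correlation) used for
efficiency curves and the weight-estimation Monte Carlo study.
"""

from __future__ import annotations

import numpy as np

from .params import MLMEParams, validate_params

__all__ = ["adcs_mci_params", "adcs_baseline_sds", "bivariate_params"]

#: Baseline standard deviations of the raw ADAS-Cog, CDR-SB and MMSE scores
#: in the pilot sample; the model parameters below are on the standardized
#: (score / baseline SD) scale.
ADCS_BASELINE_SDS = np.array([6.05, 0.78, 1.90])


def adcs_baseline_sds() -> np.ndarray:
    """Baseline SDs (raw score units) of ADAS-Cog, CDR-SB, MMSE."""
    return ADCS_BASELINE_SDS.copy()


def adcs_mci_params() -> MLMEParams:
    """Mixed-model estimates for baseline-SD-standardized ADAS/CDR/MMSE.

    Slopes are per year; the MMSE slope is negative because the MMSE declines
    while ADAS and CDR-SB rise as mild cognitive impairment progresses.
    """
    return validate_params(
        MLMEParams(
            beta=np.array([0.29, 0.74, -0.32]),
            sigma_b=np.array(
                [
                    [0.10, 0.28, -0.11],
                    [0.28, 1.04, -0.38],
                    [-0.11, -0.38, 0.17],
                ]
            ),
            sigma_e=np.array(
                [
                    [0.24, 0.05, -0.06],
                    [0.05, 0.51, -0.07],
                    [-0.06, -0.07, 0.63],
                ]
            ),
            test_names=("ADAS", "CDR", "MMSE"),
        )
    )


def bivariate_params(rho_slp: float) -> MLMEParams:
    """Two-test configuration with slope correlation ``rho_slp``.

    Test "Best" (slope variance 0.5, residual variance 2.0) is the more
    efficient single test for multi-year designs; "Worst" (slope variance
    2.0, residual variance 0.5) is less efficient.  Both have unit fixed
    slope.  Intercepts are zero with Cov(a) equal to the slope covariance and
    intercept-slope correlations 0.5 (same test) and 0.5 * rho_slp (cross).
    """
    rho = float(rho_slp)
    if not -1.0 < rho < 1.0:
        raise ValueError("rho_slp must lie in (-1, 1)")
    cov = rho * np.sqrt(0.5 * 2.0)
    return validate_params(
        MLMEParams(
            beta=np.array([1.0, 1.0]),
            sigma_b=np.array([[0.5, cov], [cov, 2.0]]),
            sigma_e=np.array([[2.0, 0.0], [0.0, 0.5]]),
            test_names=("Best", "Worst"),
        )
    )
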