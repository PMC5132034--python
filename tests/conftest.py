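import numpy as np
import pytest

from lmecomposite import (
    MLMEParams,
    TrialDesign,
    adcs_mci_params,
    bivariate_params,
    validate_params,
)


@pytest.fixture
def adcs():
    return adcs_mci_params()


@pytest.fixture
def annual_3yr():
    """Three-year trial with annual visits: t = [0, 1, 2, 3]."""
    return TrialDesign(np.array([0.0, 1.0, 2.0, 3.0]))


@pytest.fixture(params=[0.2, 0.5, 0.8])
def bivariate(request):
    return bivariate_params(request.param)


def random_pd_instance(rng, m=None):
    """A random valid parameter set: PD covariances, nonzero slopes."""
    if m is None:
        m = int(rng.integers(2, 5))
    a = rng.standard_normal((m, m))
    sigma_b = a @ a.T + 0.1 * np.eye(m)
    c = rng.standard_normal((m, m))
    sigma_e = c @ c.T + 0.1 * np.eye(m)
    beta = rng.standard_normal(m)
    while not np.any(beta != 0.0):  # pragma: no cover
        beta = rng.standard_normal(m)
    return validate_params(MLMEParams(beta=beta, sigma_b=sigma_b, sigma_e=sigma_e))
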