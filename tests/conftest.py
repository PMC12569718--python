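import numpy as np
import pytest

import airshift as a


@pytest.fixture(scope="session")
def discrete_cohort():
    """Discrete DGP cohort where saturated learners are exactly correct."""
    dgp = a.BinaryConfounderDGP(n_subjects=2000, n_years=2, seed=3)
    return dgp, dgp.generate()


@pytest.fixture(scope="session")
def shift_policy():
    """Threshold policy mapping the discrete exposure onto its own support:
    d(10.0) = 9.5 (strictly above δ = 9.9), d(9.5) = 9.5."""
    return a.Policy(kind="threshold", threshold=9.9, reduction=0.05)


@pytest.fixture(scope="session")
def small_params():
    return a.DGPParams(n_subjects=800, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
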