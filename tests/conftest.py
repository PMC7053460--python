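import numpy as np
import pytest

from frlx import FRLXParams, weibull_baseline


@pytest.fixture(scope="session")
def base():
    return weibull_baseline()


@pytest.fixture(scope="session")
def frlw_params():
    """Reference FRL-Weibull parameters used across the suite."""
    return FRLXParams(sigma=1.3, xi=(0.7, 0.4))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
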