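import numpy as np
import pytest

from telosim import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_params():
    return SimParams()


@pytest.fixture
def noisy_params():
    """Default cohort with the typical empirical error sigma of 0.05 cycles."""
    return SimParams(sigma_eps_t=0.05, sigma_eps_s=0.05, seed=7)
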