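import numpy as np
import pytest
from hypothesis import settings

from taukinetics import ModelConfig, RateConstants

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def default_config() -> ModelConfig:
    return ModelConfig(x_a=3.0, f_a=2000.0, m0=10.0)


@pytest.fixture
def generic_params() -> RateConstants:
    """A forward-dominated parameter set with all four processes active."""
    return RateConstants(k_n=1e-4, k_n_rev=0.5, k_plus=0.05, k_off=0.05, n_c=2)


@pytest.fixture
def time_grid() -> np.ndarray:
    return np.linspace(0.0, 10.0, 201)
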