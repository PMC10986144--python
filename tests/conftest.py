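import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cueqs.core import ModelParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params() -> ModelParams:
    """Reference parameter set: c0=1, c=0.3, s=r=0.01, b=0.5, kappa=Q=3,
    N=9, sigma=1."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240402)
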