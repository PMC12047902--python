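import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params():
    from spinedgg import ModelParams
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
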