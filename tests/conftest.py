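import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230703)


@pytest.fixture
def small_two_sample():
    """A strong-instrument two-sample MR dataset with theta = 0.3."""
    from targetmr.synthetic import TwoSampleConfig, simulate_two_sample

    return simulate_two_sample(TwoSampleConfig(theta=0.3, k=5, seed=11))
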