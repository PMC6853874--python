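import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def control_pool():
    """A fixed empirical autofluorescence pool (control-normalized units)."""
    rng = np.random.default_rng(20260925)
    return rng.gamma(shape=1 / 0.09, scale=0.09, size=20_000)
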