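import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcloop.networks import two_population_network, three_population_network

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_pop_net():
    """Minimal loop at the ghost-transient operating point (K_C=1.2, K_T=5.5)."""
    return two_population_network(k_c=1.2, k_t=5.5, n=1000)


@pytest.fixture(scope="session")
def three_pop_net():
    """θ/α loop with the package's default fixed thalamus→cortex couplings."""
    return three_population_network(2.0, 1.0, 1.0, 0.6, n=1000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
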