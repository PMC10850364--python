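import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neoconn as nc

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_config():
    """Short-duration configuration for unit tests (keeps filters/volumes valid)."""
    return nc.SimulationConfig(n_per_group=4, duration_s=120.0, seed=99)


@pytest.fixture(scope="session")
def small_cohort(fast_config):
    return nc.simulate_cohort(fast_config)


def random_connectivity_map(rng, n=8, labels=None, signal_type="HbO"):
    """A valid random correlation-like symmetric map."""
    x = rng.standard_normal((n, 50))
    w = np.corrcoef(x)
    labels = labels or tuple(f"n{i}" for i in range(n))
    return nc.ConnectivityMap(w, labels, signal_type)
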