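import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from herdcycles.cycles import TimeSeries, test_cyclicity
from herdcycles.synthetic import SyntheticSpec, generate_herds
from herdcycles.trophic import ModelParameters, simulate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def base_trajectory(default_params):
    """The standard 3000-year run (1500-year burn-in) of the default model."""
    return simulate(default_params)


@pytest.fixture(scope="session")
def base_metrics(base_trajectory):
    ts = TimeSeries(np.round(base_trajectory.times).astype(int), base_trajectory.N)
    return test_cyclicity(ts, seed=1)


@pytest.fixture(scope="session")
def default_synthetic():
    """The default 43-herd synthetic survey collection."""
    return generate_herds(SyntheticSpec(seed=0))


def ar1_series(rng, length, rho=0.7, obs_sd=0.5, warmup=50):
    """An OU null draw: AR(1) process plus white observation noise."""
    e = rng.standard_normal(length + warmup)
    x = np.zeros(length + warmup)
    for t in range(1, length + warmup):
        x[t] = rho * x[t - 1] + e[t]
    return x[warmup:] + obs_sd * rng.standard_normal(length)
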