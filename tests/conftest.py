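import numpy as np
import pytest
from hypothesis import settings

from ecoclim import (
    ClimateGenConfig,
    brassica_napus_parameters,
    generate_climate,
    load_parameters,
    run_grid,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return brassica_napus_parameters()


@pytest.fixture(scope="session")
def perturbation_table():
    return load_parameters()[1]


@pytest.fixture(scope="session")
def small_grid():
    """A coarse two-hemisphere world: cheap but spans all suitability regimes."""
    return generate_climate(ClimateGenConfig(n_lat=12, n_lon=3, lat_range=(-60, 60), seed=7))


@pytest.fixture(scope="session")
def small_results(small_grid, params):
    return run_grid(small_grid, params)


def random_normals(rng):
    """Random but physically ordered monthly normals."""
    base = rng.uniform(-15, 25)
    amp = rng.uniform(0, 15)
    phase = rng.uniform(0, 12)
    m = np.arange(1, 13)
    tavg = base + amp * np.cos(2 * np.pi * (m - phase) / 12) + rng.normal(0, 2, 12)
    spread = rng.uniform(2, 12)
    precip = rng.uniform(0, 200, 12)
    return tavg - spread / 2, tavg + spread / 2, precip
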