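import numpy as np
import pytest

import cpforage as cp


@pytest.fixture(scope="session")
def small_grid():
    return cp.GridSpec(lon0=-173.5, lat0=55.0, dlon=0.18, dlat=0.09, nlon=24, nlat=24)


@pytest.fixture(scope="session")
def small_env(small_grid):
    return cp.make_environment(small_grid, years=[2015, 2016], seed=7)


@pytest.fixture(scope="session")
def small_trips(small_env):
    return cp.simulate_tracks(small_env, animals=4, trips_per_animal=2, seed=7)


@pytest.fixture(scope="session")
def small_reps(small_trips, small_env):
    return cp.build_replicates(small_trips, small_env, n_replicates=3, seed=7,
                               n_candidates=15)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
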