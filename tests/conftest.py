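import numpy as np
import pytest

from replitime.fixtures import FixtureSpec, make_ipls_fixture
from replitime.replication_engine import SimConfig, run_population


@pytest.fixture(scope="session")
def clustered_fixture():
    """Clustered-site landscape: 2000 bins, 5 clusters of 10 sites."""
    return make_ipls_fixture(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def clustered_population(clustered_fixture):
    """Asynchronous population over the clustered landscape (N=8, 500
    cycles, pinned seed) shared by emergence/orientation/gating tests."""
    cfg = SimConfig(ipls=clustered_fixture.ipls, n_factors=8, n_cycles=500, seed=7)
    return run_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
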