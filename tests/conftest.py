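import numpy as np
import pytest

from permcycle.synthetic import (
    SyntheticConfig,
    generate_filter_fixture,
    generate_knockon_trajectory,
)


@pytest.fixture(scope="session")
def filter_universe():
    return generate_filter_fixture()


@pytest.fixture(scope="session")
def direct_run():
    """Noise-free direct knock-on run with 5 planted permeations."""
    cfg = SyntheticConfig(mechanism="direct_knockon", n_permeations=5,
                          noise=0.0, seed=11)
    return generate_knockon_trajectory(cfg)


@pytest.fixture(scope="session")
def soft_run():
    """Noise-free soft knock-on run with 4 planted permeations."""
    cfg = SyntheticConfig(mechanism="soft_knockon", n_permeations=4,
                          noise=0.0, seed=12)
    return generate_knockon_trajectory(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_stochastic(rng, n, concentration=2.0):
    return rng.dirichlet(np.full(n, concentration), size=n)
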