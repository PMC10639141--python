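import numpy as np
import pytest

from forestagb import synthetic


@pytest.fixture(scope="session")
def small_config():
    """A light simulation (30 plots) for wiring tests."""
    return synthetic.SimConfig(n_plots=30, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthetic.make_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The calibrated default study: 200 plots, seeded.  Session-scoped —
    it backs several recovery/consistency tests."""
    return synthetic.make_dataset(synthetic.SimConfig(n_plots=200, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
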