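import numpy as np
import pytest

from ossr.phantom import DegradationSpec, PhantomSpec, make_pair
from ossr.simplenet import NetworkConfig
from ossr.train import TrainingConfig


@pytest.fixture(scope="session")
def phantom_pair():
    """One 128x128 phantom pair with the default degradation."""
    return make_pair(0, PhantomSpec(), DegradationSpec(), master_seed=7)


@pytest.fixture(scope="session")
def small_pair():
    """A 64x64 pair for fast training tests."""
    return make_pair(0, PhantomSpec(size=64), DegradationSpec(), master_seed=11)


@pytest.fixture
def tiny_net_cfg():
    return NetworkConfig(channels=8)


@pytest.fixture
def tiny_train_cfg():
    return TrainingConfig(crop_size=32, check_period=10, fit_window=3,
                          max_steps=60, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
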