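import numpy as np
import pytest

import hnet
from hnet import DGPSpec, DoseGrid, TrainConfig


@pytest.fixture(scope="session")
def nie_instance():
    """One benchmark instance (train, test, oracle), fixed seed."""
    return hnet.generate_nie2021(DGPSpec(seed=20210321))


@pytest.fixture(scope="session")
def grid65():
    return DoseGrid.uniform(0.0, 1.0, 65)


@pytest.fixture(scope="session")
def fast_config():
    """Abbreviated training schedule for tests that need a fitted model."""
    return TrainConfig(batch_size=64, max_epochs=120)


@pytest.fixture(scope="session")
def fitted_hnet(nie_instance, fast_config):
    train, _, _ = nie_instance
    return hnet.fit(train, fast_config, seed=11)


@pytest.fixture(scope="session")
def fitted_slearner(nie_instance, fast_config):
    train, _, _ = nie_instance
    return hnet.fit_slearner(train, fast_config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
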