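import numpy as np
import pytest

from stable.synthetic import NoiseModel, make_dataset
from stable.training import TaskConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 32x32 two-domain dataset for smoke-testing the training loop."""
    return make_dataset(seed=11, n_train=6, n_test=2, image_size=(32, 32),
                        n_cells=2, test_timepoints=8)


@pytest.fixture()
def tiny_config():
    """Config matching the tiny dataset: 32x32 patches, few iterations."""
    cfg = TaskConfig.from_name("synthetic")
    cfg.patch_size = 32
    cfg.iterations = 10
    cfg.checkpoint_every = 10**6
    cfg.seed = 7
    return cfg
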