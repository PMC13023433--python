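import numpy as np
import pytest

from mibci.model import CBTNet, ModelConfig
from mibci.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature decoder config for fast structural tests."""
    return ModelConfig(
        n_channels=3, n_samples=64, conv_out_channels=(4, 4, 6, 6),
        lstm_hidden=5, patch_size=2, stride=1, embed_dim=8, tf_layers=1,
        n_heads=2, n_classes=3, conv_dropout=0.0, lstm_dropout=0.0,
        tf_dropout=0.0,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return CBTNet(tiny_config, seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """2 subjects x 8 trials/class synthetic set (unit-test fixture scale)."""
    return generate_dataset(SimConfig(n_subjects=2, trials_per_class=8, master_seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
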