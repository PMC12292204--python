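import numpy as np
import pytest

from eegcam.model import ModelConfig
from eegcam.montage import build_montage
from eegcam.synth import EpochSpec
from eegcam.training import TrainConfig


@pytest.fixture(scope="session")
def montage60():
    return build_montage(60)


@pytest.fixture(scope="session")
def epoch_spec():
    """The study's epoch geometry: 60 ch x 320 samples, -80..1200 ms, 250 Hz."""
    return EpochSpec()


@pytest.fixture(scope="session")
def mini_spec():
    """Desk-scale geometry for training-heavy property tests."""
    return EpochSpec(fs=125.0, t_start=-80.0, t_end=560.0, n_channels=60,
                     n_samples=80)


@pytest.fixture(scope="session")
def mini_model_cfg(mini_spec):
    return ModelConfig(n_channels=60, n_samples=mini_spec.n_samples,
                       spatial_filters=8, temporal_kernel_len=16,
                       depth_multiplier=2)


@pytest.fixture(scope="session")
def mini_train_cfg():
    return TrainConfig(max_epochs=25, patience=6)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
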