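import numpy as np
import pytest

from wfpn import nn
from wfpn.model import WFPNClassifier, build_model
from wfpn.pipeline import TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_tiny_model(seed: int = 0, channels: int = 32, num_classes: int = 4) -> WFPNClassifier:
    """A small seeded model (tiny trunk, narrow neck) for fast tests."""
    nn.manual_seed(seed)
    return build_model(
        {
            "backbone": "tiny",
            "neck": {"channels": channels},
            "head": {"num_classes": num_classes, "hidden": channels},
        }
    )


def tiny_train_config(**overrides) -> TrainConfig:
    """Training config sized for the tiny trunk on 32 x 32 inputs."""
    defaults = dict(backbone="tiny", channels=32, hidden=32, image_size=32, epochs=5, seed=0)
    defaults.update(overrides)
    return TrainConfig(**defaults)


@pytest.fixture
def tiny_model():
    return make_tiny_model()
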