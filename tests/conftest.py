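import numpy as np
import pytest

from histofusion import nn
from histofusion.config import (BackboneConfig, FusionConfig, ModelConfig,
                                VitConfig)


@pytest.fixture(autouse=True)
def _seed_nn():
    nn.manual_seed(0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_config(n_classes: int = 4) -> ModelConfig:
    """Smallest config preserving the structural contracts (five CNN stages,
    stride 32, three taps ending at the final layer)."""
    return ModelConfig(
        n_classes=n_classes,
        cnn=BackboneConfig(stem_channels=4, stage_channels=(4, 8, 8, 16),
                           stage_blocks=(1, 1, 1, 1), se_reduction=2,
                           embed_dim=16),
        vit=VitConfig(patch_size=16, dim=16, depth=3, heads=2, mlp_ratio=1.0,
                      tap_layers=(1, 2, 3)),
        fusion=FusionConfig(dim=16, heads=2, dropout=0.0),
    )


@pytest.fixture
def tiny_model():
    from histofusion.fusion import HistoFusionNet
    return HistoFusionNet(tiny_config(), image_size=64)


@pytest.fixture
def image_batch(rng):
    return rng.random((2, 3, 64, 64), dtype=np.float64).astype(np.float32)
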