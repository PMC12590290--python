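import numpy as np
import pytest

from gtpick import nn
from gtpick.model import ModelConfig, ParticleDetector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


TINY = ModelConfig(hidden_dim=32, n_heads=4, n_encoder_layers=1, n_decoder_layers=2,
                   groups=2, queries_per_group=5, dropout=0.1, dim_feedforward=64,
                   backbone="tiny")


@pytest.fixture
def tiny_model():
    nn.manual_seed(7)
    return ParticleDetector(TINY)


def make_model(cfg: ModelConfig, seed: int = 7) -> ParticleDetector:
    nn.manual_seed(seed)
    return ParticleDetector(cfg)
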