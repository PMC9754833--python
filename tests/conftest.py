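import numpy as np
import pytest
from hypothesis import settings

from ctsr.model import ModelConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    """Smallest non-degenerate model, float64 for numeric comparisons."""
    return ModelConfig(scale=2, in_channels=1, embed_dim=8, num_atbs=1,
                       stls_per_atb=2, window_size=4, num_heads=2,
                       dtype="float64", init_seed=3)


@pytest.fixture
def small_cfg():
    """Small float32 model used for pipeline-level tests."""
    return ModelConfig(scale=2, in_channels=1, embed_dim=16, num_atbs=1,
                       stls_per_atb=2, window_size=8, num_heads=2, init_seed=0)
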