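import numpy as np
import pytest

from sizereg import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dilution_config():
    """Noiseless asymmetric budding dilution at defaults (fixed point Vi* = 2)."""
    return ModelConfig(mechanism="dilution", mean_x=0.5)


@pytest.fixture
def accumulation_config():
    """Noiseless asymmetric budding accumulation at defaults."""
    return ModelConfig(mechanism="accumulation", mean_x=0.5)
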