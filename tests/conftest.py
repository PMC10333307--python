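import numpy as np
import pytest

from hyperseg.model import HyperbolicSegModel, ModelConfig
from hyperseg.synthetic import make_fixture_set


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def small_model_config(**kw) -> ModelConfig:
    """A desk-test model well below tiny_config, for second-scale tests."""
    base = dict(image_size=64, patch=16, width=32, depth=2, heads=2, ffn=64,
                interactions=1, adapter_heads=2, cffn_hidden=8, embed_dim=8,
                num_classes=5, curvature=1.0)
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture
def small_model():
    return HyperbolicSegModel(small_model_config(), np.random.default_rng(3))


@pytest.fixture(scope="session")
def fixture_samples():
    """Four small synthetic fundus samples shared across the session."""
    return make_fixture_set(seed=11, n=4, size=64)
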