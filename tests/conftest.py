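import numpy as np
import pytest

import hhbsnet as hb
from hhbsnet import nn


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def seeded_init():
    """Deterministic parameter initialization for every test that builds layers."""
    nn.manual_seed(1234)
    return 1234


@pytest.fixture(scope="session")
def tiny_scene_batch():
    """Eight 64x64 synthetic scenes as stacked arrays (shared, read-only)."""
    recs = hb.generate_dataset(8, hb.SceneSpec(image_size=64), seed=7)
    images = np.stack([r["image"].astype(np.float64) for r in recs])
    masks = np.stack([r["mask"] for r in recs])
    return images, masks
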