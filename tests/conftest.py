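import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from immunoaizer import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def scene_config():
    return SceneConfig(seed=0)


@pytest.fixture
def small_scene_config():
    """32x32 scenes for fast training unit tests (generator-only)."""
    return SceneConfig(height=32, width=32, blob_count_range=(1, 3), blob_radius_range=(3, 7), seed=0)


def random_prob_map(rng, h=4, w=4, c=4):
    s = rng.random((h, w, c)) + 1e-3
    return s / s.sum(axis=-1, keepdims=True)
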