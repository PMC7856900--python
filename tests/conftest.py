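import numpy as np
import pytest

from pamrestore.degrade import DegradationSpec, degrade_scene
from pamrestore.phantom import generate_scenes, generate_vessel_tree, rasterize_scene


@pytest.fixture(scope="session")
def small_scene():
    """One 64x64 rendered phantom scene."""
    tree = generate_vessel_tree(seed=7, n_roots=3, max_depth=3, field_size=(64, 64))
    return rasterize_scene(tree)


@pytest.fixture(scope="session")
def scene_batch():
    """Four 64x64 scenes with matched degraded acquisitions (f=1/2, s=2)."""
    scenes = generate_scenes(4, seed=11, field_size=(64, 64))
    pairs = [
        degrade_scene(s, DegradationSpec(0.5, 2, 0.05, seed=100 + i))
        for i, s in enumerate(scenes)
    ]
    return scenes, pairs


@pytest.fixture
def rng():
    return np.random.default_rng(42)
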