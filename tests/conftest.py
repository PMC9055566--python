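import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fbastack import RGBImage, StackParams, generate_scene, render_focal_stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """A small random 8-bit color image as RGBImage."""
    return RGBImage(rng.integers(0, 256, size=(24, 32, 3)).astype(np.float64))


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(96, 80, seed=7)


@pytest.fixture(scope="session")
def small_stack(small_scene):
    """A 5-plane noisy stack at desk scale, shared across tests."""
    return render_focal_stack(
        small_scene, StackParams(n_planes=5, blur_gain=3.0, noise_sigma=1.0, seed=7)
    )
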