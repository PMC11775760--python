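import numpy as np
import pytest

from laiscape.geostats import VariogramModel
from laiscape.grid import GridSpec
from laiscape.scene import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A 48x48 scene shared by read-only tests."""
    cfg = SceneConfig(rows=48, cols=48, seed=11, plot_count=20, track_spacing=120.0)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def default_scene():
    """Default-sized scene (128x128, 51 plots) shared by read-only tests."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture
def unit_spherical():
    return VariogramModel("spherical", nugget=0.0, partial_sill=1.0, range_a=300.0)


@pytest.fixture
def grid64():
    return GridSpec(64, 64, 15.0)
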