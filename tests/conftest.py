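import numpy as np
import pytest

from croprow import synthfield


@pytest.fixture(scope="session")
def small_scene_config():
    """A compact 3-row scene used across geometry tests."""
    return synthfield.SceneConfig(
        image_height=384, image_width=384, n_rows=3, row_spacing=110,
        plant_spacing=48, plant_radius_range=(10.0, 16.0), weed_density=4.0,
        gap_probability=0.0, row_slope_range=(-0.03, 0.03), seed=7)


@pytest.fixture(scope="session")
def small_scene(small_scene_config):
    return synthfield.generate_scene(small_scene_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
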