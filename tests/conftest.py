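import numpy as np
import pytest

from needlegrade import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete scene: 30 trees per class."""
    return SceneConfig(n_trees_per_class=30, seed=42)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def small_ms_scene():
    return SceneConfig(n_trees_per_class=30, ms_enabled=True, seed=42)


@pytest.fixture(scope="session")
def noiseless_config():
    """Zero colour noise, zero texture grain, no shadows: collapse case."""
    return SceneConfig(
        n_trees_per_class=5, class_color_sd=0.0,
        texture_grain={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
        shadow_fraction=0.0, background_noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240304)
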