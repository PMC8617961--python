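import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene_config():
    from ophiocount import SceneConfig

    return SceneConfig(width=320, height=320, n_stars=(4, 8))


@pytest.fixture(scope="session")
def small_scene(small_scene_config):
    from ophiocount import generate_scene

    return generate_scene(small_scene_config, seed=7)


@pytest.fixture(scope="session")
def tiny_train_config():
    from ophiocount import TrainConfig

    return TrainConfig(patch_size=48, stride=24, epochs=3, seed=0)


def draw_disc(shape, center, radius):
    """Boolean disc mask helper used across counting tests."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
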