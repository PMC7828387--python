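import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vesiflow as vf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_radial_movie():
    """Short mixed inward/outward radial scene with ground truth."""
    cfg = vf.SceneConfig(seed=7, n_frames=6)
    stack, truth = vf.generate_movie(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def small_radial_flows(small_radial_movie):
    _, stack, _ = small_radial_movie
    return vf.compute_flow_series(stack)


def gaussian_blob(shape, center, sigma, amplitude=1.0):
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return amplitude * np.exp(
        -((rows - center[0]) ** 2 + (cols - center[1]) ** 2) / (2 * sigma**2)
    )
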