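import numpy as np
import pytest

import mabeauty as mb
from mabeauty.synth import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def schema():
    return mb.default_schema()


@pytest.fixture(scope="session")
def registry():
    return mb.default_registry()


@pytest.fixture(scope="session")
def mean_face():
    return mb.LandmarkSet(mb.mean_shape(), source_id="mean")


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-face synthetic cohort with mild asymmetry, shared across tests."""
    cfg = SyntheticConfig(n_faces=120, asymmetry_level=1.5, seed=7)
    return generate_dataset(cfg)


def random_similarity(rng: np.random.Generator):
    """A random rotation + isotropic scale + translation as (R*s, t)."""
    theta = rng.uniform(0, 2 * np.pi)
    s = float(np.exp(rng.uniform(np.log(0.2), np.log(5.0))))
    c, si = np.cos(theta), np.sin(theta)
    R = np.array([[c, -si], [si, c]]) * s
    t = rng.uniform(-200, 200, size=2)
    return R, t


def apply_similarity(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t
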