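import numpy as np
import pytest

from lasec import LandmarkConfigurationSet, sim_coord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """10 specimens x 8 landmarks in 2-D, fixed seed."""
    return sim_coord(n_specimens=10, n_landmarks=8, n_dims=2,
                     covariance=0.1, seed=42)


@pytest.fixture
def small_dataset_3d():
    """8 specimens x 6 landmarks in 3-D, fixed seed."""
    return sim_coord(n_specimens=8, n_landmarks=6, n_dims=3,
                     covariance=0.1, seed=43)


@pytest.fixture
def unit_square_set():
    """Three translated/scaled copies of the unit square plus one distinct
    quadrilateral (so constellations carry variance)."""
    square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    quad = np.array([[0.0, 0.0], [2.0, 0.1], [1.8, 1.2], [-0.1, 0.9]])
    coords = np.stack([square, square * 2.0 + 1.0, square + [3.0, -1.0], quad])
    return LandmarkConfigurationSet(coords=coords)


def random_similarity_transform(rng, d, allow_reflection=False):
    """Random rotation (optionally improper), positive scale, translation."""
    a = rng.standard_normal((d, d))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if allow_reflection and rng.random() < 0.5:
        q[:, 0] *= -1.0
    elif not allow_reflection and np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    scale = float(rng.uniform(0.2, 5.0))
    shift = rng.standard_normal(d) * 3.0
    return q, scale, shift
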