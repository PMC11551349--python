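import numpy as np
import pytest

from ramanmix import synthgen
from ramanmix.core import SpectralAxis, SpectralDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Endmember sampler scaled down for fast unit tests."""
    return synthgen.EndmemberSamplerParams(b=64, n=3)


@pytest.fixture
def tiny_chessboard():
    """A small pure-pixel dataset (3 endmembers, 64 bands, 10x10 scene)."""
    return synthgen.generate_dataset(
        "ideal",
        "chessboard",
        seed=3,
        endmember_params=synthgen.EndmemberSamplerParams(b=64, n=3),
        scene_params=synthgen.SceneParams(kind="chessboard", H=10, W=10, patch=5),
        require_full_coverage=True,
    )


@pytest.fixture
def simplex_fixture(rng):
    """n simplex vertices plus strict convex combinations of them.

    The vertices are well-separated nonnegative spectra; every other point
    is strictly interior, so pure-pixel extractors must return exactly the
    vertex rows.
    """
    n, b = 4, 30
    vertices = np.zeros((n, b))
    for i in range(n):
        vertices[i, i * 6 : i * 6 + 4] = 3.0 + i
        vertices[i] += 0.05  # keep strictly positive
    weights = rng.dirichlet(np.ones(n) * 5.0, size=100) * 0.9 + 0.025
    weights /= weights.sum(axis=1, keepdims=True)
    interior = weights @ vertices
    data = np.vstack([interior[:50], vertices, interior[50:]])
    axis = SpectralAxis(np.arange(1, b + 1, dtype=float))
    d = SpectralDataset(data, axis)
    vertex_rows = np.arange(50, 50 + n)
    return d, vertices, vertex_rows


def random_dataset(rng, n_spectra=8, n_bands=16, scene=None):
    axis = SpectralAxis(np.sort(rng.uniform(100, 3500, size=n_bands)))
    intens = rng.normal(1.0, 2.0, size=(n_spectra, n_bands))
    return SpectralDataset(intens, axis, scene_shape=scene)
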