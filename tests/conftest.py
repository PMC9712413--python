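import numpy as np
import pytest

from ramapeak.ramachandran import RamachandranMap
from ramapeak.spectral_io import PeakRegion, SpectralAxis
from ramapeak.synthetic import alanine_model


@pytest.fixture(scope="session")
def model():
    return alanine_model()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_peak():
    """Separable 4D Gaussian peak on descending ppm axes."""
    axes = (
        SpectralAxis("H", 12, 9.0, -0.2),
        SpectralAxis("N", 12, 127.0, -0.8),
        SpectralAxis("CA", 12, 58.0, -0.6),
        SpectralAxis("CB", 12, 25.0, -0.6),
    )
    centers = (8.0, 122.0, 54.5, 21.0)
    sig = (0.4, 1.6, 1.2, 1.2)
    parts = [np.exp(-0.5 * ((ax.ppm - c) / s) ** 2)
             for ax, c, s in zip(axes, centers, sig)]
    arr = (parts[0][:, None, None, None] * parts[1][None, :, None, None]
           * parts[2][None, None, :, None] * parts[3][None, None, None, :])
    return PeakRegion(arr, axes)


def random_unfolded_map(rng) -> RamachandranMap:
    d = rng.random((18, 18))
    return RamachandranMap(d / d.sum(), folded=False, normalized=True)


def random_folded_map(rng) -> RamachandranMap:
    d = rng.random((10, 18))
    return RamachandranMap(d / d.sum(), folded=True, normalized=True)
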