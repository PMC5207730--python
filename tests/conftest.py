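import numpy as np
import pytest

from roughseg.grid import ImageGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_level_noisy(rng):
    """8x8 two-level image with mild noise, plus its clean level values."""
    base = np.zeros((8, 8))
    base[:, 4:] = 1.0
    noisy = base + rng.normal(0.0, 0.05, base.shape)
    return ImageGrid(noisy), (0.0, 1.0)


def pad_replicate(data: np.ndarray) -> np.ndarray:
    return np.pad(data, ((1, 1), (1, 1), (0, 0)), mode="edge")


def naive_neighborhood_distance(image: ImageGrid, row: int, col: int,
                                level) -> float:
    """Eq-by-eq double-loop distance oracle: 3x3 window, replicate padding."""
    g = np.broadcast_to(np.atleast_1d(np.asarray(level, float)),
                        (image.n_channels,))
    padded = pad_replicate(image.data)
    total = 0.0
    for dr in range(3):
        for dc in range(3):
            diff = padded[row + dr, col + dc] - g
            total += float(diff @ diff)
    return total / (9.0 * (image.intensity_max - image.intensity_min))
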