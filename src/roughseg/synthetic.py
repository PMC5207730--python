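"""Synthetic piecewise-constant phantoms and the two noise models.

The phantoms emulate the synthetic test images used throughout the
evaluation: 128 x 128 piecewise-constant images whose labels take evenly
spaced luminances in [0, 1] (four labels at [0, 1/3, 2/3, 1] or five at
[0, 1/4, 2/4, 3/4, 1]), corrupted either by additive Gaussian noise
(variance 0.07) or multiplicative speckle noise (variance 0.04). Three
geometric layouts of comparable region structure are provided;
`concentric` (nested shapes on a background) is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ImageGrid

LAYOUTS = ("concentric", "quadrant", "stripes")

#: label luminances of the four- and five-class phantoms
FOUR_LABEL_LUMINANCES = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)
FIVE_LABEL_LUMINANCES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and luminances of one synthetic phantom."""

    size: tuple[int, int] = (128, 128)
    luminances: tuple = FOUR_LABEL_LUMINANCES
    layout: str = "concentric"
    seed: int = 0

    def __post_init__(self):
        lum = tuple(float(v) for v in self.luminances)
        if len(lum) < 2 or any(b <= a for a, b in zip(lum, lum[1:])):
            raise ValueError("luminances must be strictly increasing")
        if min(lum) < 0 or max(lum) > 1:
            raise ValueError("luminances must lie in [0, 1]")
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}; choose from {LAYOUTS}")
        object.__setattr__(self, "luminances", lum)


def _concentric_labels(shape: tuple[int, int], n: int) -> np.ndarray:
    """Nested shapes (an outer square, then discs) on a background.

    Shape sizes are chosen so every label occupies roughly 1/n of the
    pixels: balanced class areas keep every class identifiable from the
    intensity histogram even under heavy noise.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dy, dx = rr - cy, cc - cx
    labels = np.ones(shape, dtype=np.int64)
    total = h * w
    for j in range(2, n + 1):
        area = (n - j + 1) / n * total  # labels j..n together
        if j == 2:
            half = np.sqrt(area) / 2.0
            inside = (np.abs(dy) <= half) & (np.abs(dx) <= half)
        else:
            r = np.sqrt(area / np.pi)
            inside = dy**2 + dx**2 <= r**2
        labels[inside] = j
    return labels


def _quadrant_labels(shape: tuple[int, int], n: int) -> np.ndarray:
    """2x2 blocks, with an optional centered square for a fifth label."""
    if n not in (4, 5):
        raise ValueError("quadrant layout supports 4 or 5 labels")
    h, w = shape
    labels = np.ones(shape, dtype=np.int64)
    labels[: h // 2, w // 2:] = 2
    labels[h // 2:, : w // 2] = 3
    labels[h // 2:, w // 2:] = 4
    if n == 5:
        qh, qw = h // 4, w // 4
        labels[h // 2 - qh: h // 2 + qh, w // 2 - qw: w // 2 + qw] = 5
    return labels


def _stripe_labels(shape: tuple[int, int], n: int) -> np.ndarray:
    h = shape[0]
    edges = np.linspace(0, h, n + 1).astype(int)
    labels = np.empty(shape, dtype=np.int64)
    for j in range(n):
        labels[edges[j]: edges[j + 1], :] = j + 1
    return labels


def make_phantom(spec: PhantomSpec) -> tuple[ImageGrid, np.ndarray]:
    """Build a piecewise-constant phantom and its ground-truth label map.

    Returns the clean image (label j painted at luminance j) and integer
    labels in 1..n. Every label is checked to occupy at least 1% of the
    pixels so all classes remain learnable.
    """
    n = len(spec.luminances)
    builders = {"concentric": _concentric_labels, "quadrant": _quadrant_labels,
                "stripes": _stripe_labels}
    labels = builders[spec.layout](spec.size, n)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    if np.any(counts < 0.01 * labels.size):
        raise ValueError("a label occupies less than 1% of the phantom")
    lum = np.asarray(spec.luminances)
    image = lum[labels - 1]
    return ImageGrid(image), labels


def add_gaussian_noise(image: ImageGrid, mean: float, variance: float,
                       seed: int = 0, clip: bool = False) -> ImageGrid:
    """Additive Gaussian noise x + n, n ~ Normal(mean, variance).

    Unclipped by default (the segmentation model is bounded-support;
    clipping is available for display or 8-bit export).
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    rng = np.random.default_rng(seed)
    noisy = image.data + rng.normal(mean, np.sqrt(variance), image.data.shape)
    if clip:
        noisy = np.clip(noisy, 0.0, 1.0)
    return ImageGrid(noisy)


def add_speckle_noise(image: ImageGrid, variance: float, seed: int = 0,
                      clip: bool = False) -> ImageGrid:
    """Multiplicative speckle noise x + x * n, n ~ Normal(0, variance).

    This is the MATLAB ``imnoise(..., 'speckle')`` convention: the noise
    scales with the local intensity, so dark regions stay clean and
    bright regions get the widest (and skewed) intensity spread.
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    rng = np.random.default_rng(seed)
    n = rng.normal(0.0, np.sqrt(variance), image.data.shape)
    noisy = image.data * (1.0 + n)
    if clip:
        noisy = np.clip(noisy, 0.0, 1.0)
    return ImageGrid(noisy)
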