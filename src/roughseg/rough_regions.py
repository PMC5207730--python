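"""Adaptive rough regions and the graded bounded-support indicator.

Each cluster k partitions the image into three rough regions — positive
(Po: certainly a member), boundary (Bo: possibly a member) and negative
(Ne: not a member) — by comparing a neighborhood-averaged squared distance
between the pixel and the cluster mean against two thresholds (t1, t2)
estimated once per image from the full set of intensity levels:

    d_i(g) = sum_{m in 3x3 window of i} ||x_m - g||^2 / (9 (J_max - J_min))
    t1 = mean_i min_g d_i(g),   t2 = mean_i mean_g d_i(g)

The graded indicator replaces the hard 0/1 support function of bounded
mixture models: H = 1 on Po, a linear ramp (t2 - d)/(t2 - t1) on Bo, and
0 on Ne, so membership in a cluster's bounded support degrades
continuously with distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import ImageGrid

# region codes, ordered so that larger = more certainly a member
NE, BO, PO = 0, 1, 2

#: window side and pixel count of the rough-region neighborhood
WINDOW = 3
N_WINDOW = WINDOW * WINDOW


@dataclass(frozen=True)
class ThresholdPair:
    """Adaptive distance thresholds separating Po / Bo / Ne."""

    t1: float
    t2: float

    def __post_init__(self):
        if not (0.0 <= self.t1 <= self.t2 + 1e-12):
            raise ValueError(f"need 0 <= t1 <= t2, got t1={self.t1}, t2={self.t2}")


@dataclass(frozen=True)
class RoughPartition:
    """Per-pixel per-cluster rough-region labels, distances and indicators.

    ``region``, ``distance`` and ``indicator`` all have shape
    ``(height, width, K)``; ``region`` holds the codes PO / BO / NE.
    """

    region: np.ndarray
    distance: np.ndarray
    indicator: np.ndarray
    thresholds: ThresholdPair


def _neighborhood_moments(image: ImageGrid) -> tuple[np.ndarray, np.ndarray]:
    """3x3 neighborhood means of x (per channel) and of ||x||^2.

    Replicate padding keeps the window population at 9 everywhere.
    """
    x = image.data
    mean_x = np.empty_like(x)
    for c in range(image.n_channels):
        mean_x[:, :, c] = ndimage.uniform_filter(x[:, :, c], size=WINDOW, mode="nearest")
    mean_sq = ndimage.uniform_filter(
        np.sum(x * x, axis=2), size=WINDOW, mode="nearest"
    )
    return mean_x, mean_sq


def _check_scale(image: ImageGrid) -> float:
    scale = image.intensity_range
    if scale <= 0:
        raise ValueError("constant image: J_max == J_min, distance scale is degenerate")
    return scale


def distance_field(image: ImageGrid, level: np.ndarray) -> np.ndarray:
    """Neighborhood-averaged squared distance of every pixel to one level.

    ``level`` is a scalar (broadcast over channels) or a length-D vector;
    returns an ``(H, W)`` array of d_i(level).
    """
    scale = _check_scale(image)
    g = np.broadcast_to(np.atleast_1d(np.asarray(level, dtype=float)),
                        (image.n_channels,))
    mean_x, mean_sq = _neighborhood_moments(image)
    # E||x - g||^2 over the window = E||x||^2 - 2 g.E[x] + ||g||^2
    d = mean_sq - 2.0 * np.tensordot(mean_x, g, axes=([2], [0])) + float(g @ g)
    np.maximum(d, 0.0, out=d)
    return d / scale


def distance_to_level(image: ImageGrid, pixel: tuple[int, int], level) -> float:
    """d_i(g) for a single pixel (row, col); see :func:`distance_field`."""
    return float(distance_field(image, level)[pixel])


def default_levels(image: ImageGrid, n_float_levels: int = 64) -> np.ndarray:
    """Candidate intensity levels g_j used for threshold estimation.

    Integer-valued 8-bit images enumerate all 256 levels; float or
    multichannel images use ``n_float_levels`` levels uniformly spaced
    between J_min and J_max (each level broadcast across channels).
    """
    if image.integer_levels and image.intensity_max <= 255:
        return np.arange(256, dtype=float)
    return np.linspace(image.intensity_min, image.intensity_max, n_float_levels)


def compute_thresholds(image: ImageGrid, levels: np.ndarray | None = None) -> ThresholdPair:
    """Estimate (t1, t2) from the per-pixel distance vector over all levels.

    t1 is the image average of each pixel's minimum distance over the
    levels, t2 the average of the mean distance; min <= mean pixelwise
    guarantees t1 <= t2.
    """
    if levels is None:
        levels = default_levels(image)
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("empty level set")
    if levels.ndim == 1:
        levels = np.repeat(levels[:, None], image.n_channels, axis=1)

    scale = _check_scale(image)
    mean_x, mean_sq = _neighborhood_moments(image)
    flat_mx = mean_x.reshape(-1, image.n_channels)  # (N, D)
    flat_sq = mean_sq.reshape(-1)  # (N,)
    # d[i, j] = E||x||^2_i - 2 g_j . E[x]_i + ||g_j||^2, all levels at once
    d = (
        flat_sq[:, None]
        - 2.0 * flat_mx @ levels.T
        + np.sum(levels * levels, axis=1)[None, :]
    )
    np.maximum(d, 0.0, out=d)
    d /= scale
    t1 = float(d.min(axis=1).mean())
    t2 = float(d.mean(axis=1).mean())
    return ThresholdPair(t1=t1, t2=max(t1, t2))


def bounded_indicator(distance, thresholds: ThresholdPair):
    """Graded membership H in [0, 1] as a function of distance.

    1 for d <= t1, the linear ramp (t2 - d)/(t2 - t1) on (t1, t2], 0
    beyond t2. Degenerate thresholds (t1 == t2) collapse the boundary
    band to a hard cut at t1.
    """
    d = np.asarray(distance, dtype=float)
    t1, t2 = thresholds.t1, thresholds.t2
    if t2 <= t1:
        warnings.warn("t1 == t2: boundary band collapsed to a hard threshold")
        out = (d <= t1).astype(float)
    else:
        out = np.clip((t2 - d) / (t2 - t1), 0.0, 1.0)
    if np.ndim(distance) == 0:
        return float(out)
    return out


def point_indicator(x, mean, thresholds: ThresholdPair, scale: float):
    """Indicator for an arbitrary intensity vector off the pixel lattice.

    Uses the neighborhood-free (n = 1) form of the distance,
    ||x - mean||^2 / scale, so the indicator can be evaluated on
    Monte-Carlo sample vectors that have no image neighborhood.
    ``x`` may be a single vector or a batch ``(..., D)``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    d = np.sum((x - mean) ** 2, axis=-1) / scale
    return bounded_indicator(d, thresholds)


def assign_rough_regions(
    image: ImageGrid, means: np.ndarray, thresholds: ThresholdPair
) -> RoughPartition:
    """Label every pixel Po/Bo/Ne for each cluster and attach indicators.

    ``means`` has shape (K, D) or (K,) for grayscale. A pixel may sit
    inside t1 for several clusters; Po is then kept only for the
    nearest cluster (ties to the lowest index) and the others are
    demoted to Bo, so hard membership is never contradictory.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    if means.shape[0] < 2:
        raise ValueError("need at least K = 2 cluster means")
    K = means.shape[0]
    H, W = image.height, image.width
    dist = np.empty((H, W, K))
    for k in range(K):
        dist[:, :, k] = distance_field(image, means[k])

    t1, t2 = thresholds.t1, thresholds.t2
    region = np.full((H, W, K), NE, dtype=np.int8)
    region[dist <= t2] = BO
    po_mask = dist <= t1
    region[po_mask] = PO

    # demote all but the argmin-distance cluster where Po overlaps
    multi = po_mask.sum(axis=2) > 1
    if np.any(multi):
        # argmin over clusters restricted to the Po candidates
        masked = np.where(po_mask, dist, np.inf)
        keep = masked.argmin(axis=2)
        demote = po_mask & (np.arange(K)[None, None, :] != keep[:, :, None])
        region[demote & multi[:, :, None]] = BO

    indicator = bounded_indicator(dist, thresholds)
    indicator[region == PO] = 1.0
    indicator[region == NE] = 0.0
    # demoted-to-Bo clusters keep the clamped ramp value (1 at d <= t1)
    return RoughPartition(region=region, distance=dist, indicator=indicator,
                          thresholds=ThresholdPair(t1, t2))
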