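"""Directional neighborhood selection and the spatial prior factors E, F.

For every pixel and cluster the 3x3 window is split into four directional
lines (horizontal, vertical, two diagonals, each holding the center and
its two collinear neighbors). The direction whose member pixels lie
closest to the cluster mean is selected,

    S*_k(i) = argmin_s sum_{m in line s} ||x_m - mu_k||,

so on an edge the along-edge line wins and smoothing never crosses the
boundary — this is the detail-preserving mechanism. The prior factors
are softmax-normalized direction-averaged sums of (posterior + prior):

    E_ik  = softmax_k [ mean_{m in line S*_k} (z_mk + pi_mk) ]      (between-cluster)
    F_ikl = softmax_l [ mean_{m in line S*_kl} (y_mkl + eta_mkl) ]  (within-cluster)
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import ImageGrid

#: binary 3x3 masks for the four directional lines, in tie-break order:
#: horizontal, vertical, NW-SE diagonal, NE-SW diagonal
DIRECTION_MASKS = np.array(
    [
        [[0, 0, 0], [1, 1, 1], [0, 0, 0]],
        [[0, 1, 0], [0, 1, 0], [0, 1, 0]],
        [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
        [[0, 0, 1], [0, 1, 0], [1, 0, 0]],
    ],
    dtype=float,
)

N_DIRECTIONS = 4
#: pixels per directional line (replicate padding keeps this constant)
LINE_SIZE = 3


def _directional_sums(field: np.ndarray) -> np.ndarray:
    """Sum of ``field`` over each directional line: (H, W, 4)."""
    out = np.empty(field.shape + (N_DIRECTIONS,))
    for s in range(N_DIRECTIONS):
        out[:, :, s] = ndimage.correlate(field, DIRECTION_MASKS[s], mode="nearest")
    return out


def select_direction(image: ImageGrid, mean) -> np.ndarray:
    """Per-pixel index of the direction closest to ``mean``: (H, W).

    Ties resolve to the lowest direction index (argmin order).
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    dist = np.sqrt(np.sum((image.data - mean) ** 2, axis=2))
    return np.argmin(_directional_sums(dist), axis=2)


def _directional_average(field: np.ndarray, chosen: np.ndarray) -> np.ndarray:
    """Average of ``field`` over each pixel's chosen directional line."""
    sums = _directional_sums(field)
    picked = np.take_along_axis(sums, chosen[:, :, None], axis=2)[:, :, 0]
    return picked / LINE_SIZE


def prior_factor_between(z: np.ndarray, pi: np.ndarray, image: ImageGrid,
                         means: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between-cluster factor E_ik and the chosen directions.

    z, pi: (N, K) in row-major pixel order; means: (K, D).
    Returns (E, chosen) with E rows summing to 1 over clusters.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    K = means.shape[0]
    H, W = image.height, image.width
    args = np.empty((H, W, K))
    chosen = np.empty((H, W, K), dtype=np.int64)
    for k in range(K):
        chosen[:, :, k] = select_direction(image, means[k])
        field = (z[:, k] + pi[:, k]).reshape(H, W)
        args[:, :, k] = _directional_average(field, chosen[:, :, k])
    # arguments are bounded in [0, 2]; plain softmax is safe
    ex = np.exp(args)
    E = (ex / ex.sum(axis=2, keepdims=True)).reshape(-1, K)
    return E, chosen.reshape(-1, K)


def prior_factor_within(y: np.ndarray, eta: np.ndarray, image: ImageGrid,
                        component_means: np.ndarray) -> np.ndarray:
    """Within-cluster factor F_ikl, summing to 1 over components.

    y, eta: (N, K, L); component_means: (K, L, D). The directional
    selection reuses the same argmin rule with the component means.
    """
    K, L = y.shape[1], y.shape[2]
    H, W = image.height, image.width
    args = np.empty((H, W, K, L))
    for k in range(K):
        for l in range(L):
            chosen = select_direction(image, component_means[k, l])
            field = (y[:, k, l] + eta[:, k, l]).reshape(H, W)
            args[:, :, k, l] = _directional_average(field, chosen)
    ex = np.exp(args)
    F = (ex / ex.sum(axis=3, keepdims=True)).reshape(-1, K, L)
    return F
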