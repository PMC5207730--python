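"""Segmentation quality metrics: CCR, Dice coefficient, PRI.

Mixture labels are arbitrary, so CCR first matches predicted clusters to
ground-truth classes by a maximum-overlap (Hungarian) assignment; Dice
operates on one binary tissue mask at a time; PRI averages pairwise
co-clustering agreement against one or more human ground truths.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import rand_score


def _as_flat_labels(a: np.ndarray) -> np.ndarray:
    return np.asarray(a).ravel()


def match_labels(seg: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Relabel ``seg`` onto ``gt``'s label set by maximum-overlap assignment.

    Builds the contingency table between the two labelings and solves the
    linear assignment that maximizes total overlap; unmatched predicted
    labels (when seg has more classes than gt) keep a fresh label.
    """
    seg_f, gt_f = _as_flat_labels(seg), _as_flat_labels(gt)
    if seg_f.shape != gt_f.shape:
        raise ValueError("segmentation and ground truth shapes differ")
    seg_vals, seg_idx = np.unique(seg_f, return_inverse=True)
    gt_vals, gt_idx = np.unique(gt_f, return_inverse=True)
    table = np.zeros((seg_vals.size, gt_vals.size), dtype=np.int64)
    np.add.at(table, (seg_idx, gt_idx), 1)
    rows, cols = linear_sum_assignment(-table)
    mapping = {}
    spare = gt_vals.max() + 1
    for r in range(seg_vals.size):
        hit = np.nonzero(rows == r)[0]
        if hit.size:
            mapping[r] = gt_vals[cols[hit[0]]]
        else:
            mapping[r] = spare
            spare += 1
    out = np.array([mapping[r] for r in range(seg_vals.size)])[seg_idx]
    return out.reshape(np.asarray(seg).shape)


def ccr(seg: np.ndarray, gt: np.ndarray) -> float:
    """Correct classification ratio after maximum-overlap label matching.

    Fraction of pixels whose matched predicted class equals the ground
    truth; 1.0 is a perfect segmentation.
    """
    matched = match_labels(seg, gt)
    return float(np.mean(_as_flat_labels(matched) == _as_flat_labels(gt)))


def dice(seg_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Dice coefficient 2|A & B| / (|A| + |B|) of two binary masks."""
    a = np.asarray(seg_mask).astype(bool).ravel()
    b = np.asarray(gt_mask).astype(bool).ravel()
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1.0 by convention")
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def pri(seg: np.ndarray, gts) -> float:
    """Probabilistic Rand index of a segmentation against >= 1 ground truths.

    For each ground truth the Rand index counts the pixel pairs whose
    same-cluster/different-cluster relation agrees; averaging over the
    ground-truth set yields the probabilistic version. The per-truth
    Rand index is computed through the contingency-table identity rather
    than the O(N^2) pair enumeration.
    """
    if isinstance(gts, np.ndarray) and gts.ndim <= 2:
        gts = [gts]
    gts = list(gts)
    if not gts:
        raise ValueError("need at least one ground truth")
    seg_f = _as_flat_labels(seg)
    scores = []
    for gt in gts:
        gt_f = _as_flat_labels(gt)
        if gt_f.shape != seg_f.shape:
            raise ValueError("segmentation and ground truth shapes differ")
        scores.append(rand_score(gt_f, seg_f))
    return float(np.mean(scores))
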