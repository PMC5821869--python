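"""Validation helpers: detection matching and simple agreement metrics."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["match_detections", "precision_recall", "r_squared"]


def match_detections(
    truth_xy: np.ndarray, detected_xy: np.ndarray, max_dist: float
) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one matching of detections to ground-truth positions.

    Solves the assignment problem on the pairwise distance matrix and
    keeps pairs closer than ``max_dist``.  Returns ``(truth_idx,
    det_idx)`` arrays of matched pairs.
    """
    truth_xy = np.asarray(truth_xy, dtype=float).reshape(-1, 2)
    detected_xy = np.asarray(detected_xy, dtype=float).reshape(-1, 2)
    if truth_xy.shape[0] == 0 or detected_xy.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = cdist(truth_xy, detected_xy)
    ti, di = linear_sum_assignment(d)
    keep = d[ti, di] <= max_dist
    return ti[keep], di[keep]


def precision_recall(
    truth_xy: np.ndarray, detected_xy: np.ndarray, max_dist: float
) -> tuple[float, float]:
    """Detection precision and recall under one-to-one matching."""
    ti, _ = match_detections(truth_xy, detected_xy, max_dist)
    n_truth = np.asarray(truth_xy).reshape(-1, 2).shape[0]
    n_det = np.asarray(detected_xy).reshape(-1, 2).shape[0]
    tp = ti.size
    precision = tp / n_det if n_det else 1.0
    recall = tp / n_truth if n_truth else 1.0
    return precision, recall


def r_squared(x, y) -> float:
    """Squared Pearson correlation between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)
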