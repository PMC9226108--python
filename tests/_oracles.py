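"""Independent brute-force reference implementations for the metric panel.

Written directly from the textbook definitions, deliberately sharing no code
with the package: confusion counts by explicit boolean sums, overlap metrics
by their formulas in python floats, HD95 by all-pairs boundary distances, and
AUC by exhaustive concordant-pair counting.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist


def oracle_confusion(pred: np.ndarray, ref: np.ndarray):
    p = np.asarray(pred).astype(bool).ravel()
    r = np.asarray(ref).astype(bool).ravel()
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    tn = int(np.sum(~p & ~r))
    return tp, fp, fn, tn


def oracle_overlap(tp: int, fp: int, fn: int, tn: int):
    """(dsc, jaccard, fn_rate, mcc, vs); NaN where the definition divides by 0."""
    dsc = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    jac = tp / (tp + fp + fn) if (tp + fp + fn) else 1.0
    fnr = fn / (tp + fn) if (tp + fn) else float("nan")
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    vs = 1 - abs(fn - fp) / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    return dsc, jac, fnr, mcc, vs


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of foreground voxels with a background face-neighbour
    (voxels on the array edge count as boundary)."""
    m = np.asarray(mask).astype(bool)
    coords = []
    offsets = []
    for ax in range(m.ndim):
        for d in (-1, 1):
            off = [0] * m.ndim
            off[ax] = d
            offsets.append(tuple(off))
    for idx in np.argwhere(m):
        for off in offsets:
            nb = tuple(idx + np.array(off))
            if any(n < 0 or n >= m.shape[i] for i, n in enumerate(nb)) or not m[nb]:
                coords.append(idx)
                break
    return np.array(coords, dtype=float)


def oracle_hd95(pred: np.ndarray, ref: np.ndarray, spacing=None) -> float:
    bp = _boundary_voxels(pred)
    br = _boundary_voxels(ref)
    if spacing is not None:
        bp = bp * np.asarray(spacing)
        br = br * np.asarray(spacing)
    d = cdist(bp, br)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))


def oracle_auc(prob: np.ndarray, ref: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2)."""
    prob = np.asarray(prob, dtype=float).ravel()
    r = np.asarray(ref).astype(bool).ravel()
    pos = prob[r][:, None]
    neg = prob[~r][None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins / (pos.size * neg.size))


def oracle_r2(x, y) -> float:
    """Coefficient of determination from the OLS normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    return float(sxy ** 2 / (sxx * syy))
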