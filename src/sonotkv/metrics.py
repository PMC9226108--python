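"""Segmentation evaluation panel: overlap, distance, correlation and AUC.

The panel mirrors standard volumetric-segmentation reporting: Dice (DSC),
Jaccard, false-negative rate, Matthews correlation coefficient, 95th-percentile
Hausdorff surface distance (HD95), volume similarity (VS) and voxelwise
ROC-AUC, plus raw confusion counts, and a slice-decile Dice profile that
localises where along the kidney a prediction degrades.

Division-by-zero conventions are explicit, returned as NaN with a flag, never
as silent zeros:

* two empty masks -> DSC/Jaccard/VS = 1, flagged ``empty_masks``;
* ``fn_rate`` undefined when the reference is empty (tp + fn = 0);
* MCC with a zero denominator -> 0 (the no-information value);
* AUC undefined when the reference is single-class;
* HD95 undefined when either mask is empty.

"FN" here is the false-negative *rate* fn / (tp + fn), i.e. 1 - sensitivity.
HD95 is reported in voxel units by default; pass spacing for millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt
from scipy.stats import rankdata

from .types import SegmentationMask


@dataclass
class MetricReport:
    dsc: float
    jaccard: float
    fn_rate: float
    mcc: float
    hd95: float
    vs: float
    auc: float
    tp: int
    fp: int
    fn: int
    tn: int
    flags: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict:
        return {k: getattr(self, k) for k in
                ("dsc", "jaccard", "fn_rate", "mcc", "hd95", "vs", "auc",
                 "tp", "fp", "fn", "tn", "flags")}


def _binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    uniq = np.unique(a)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"{name} must be binary, found values {uniq[:10]}")
    return a.astype(bool)


def confusion_counts(pred: np.ndarray, ref: np.ndarray) -> Tuple[int, int, int, int]:
    """Voxelwise (tp, fp, fn, tn); accepts arrays or SegmentationMasks."""
    p = _binary(pred.voxels if isinstance(pred, SegmentationMask) else pred, "pred")
    r = _binary(ref.voxels if isinstance(ref, SegmentationMask) else ref, "ref")
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs ref {r.shape}")
    tp = int((p & r).sum())
    fp = int((p & ~r).sum())
    fn = int((~p & r).sum())
    tn = int((~p & ~r).sum())
    return tp, fp, fn, tn


def overlap_metrics(tp: int, fp: int, fn: int, tn: int
                    ) -> Tuple[float, float, float, float, float, List[str]]:
    """(dsc, jaccard, fn_rate, mcc, vs, flags) from confusion counts."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    flags: List[str] = []
    if tp + fp + fn + tn == 0:
        raise ValueError("all confusion counts are zero; undefined report")

    denom = 2 * tp + fp + fn
    if denom == 0:
        # both masks empty: perfect (vacuous) agreement, flagged
        flags.append("empty_masks")
        dsc = jaccard = vs = 1.0
    else:
        dsc = 2.0 * tp / denom
        jaccard = tp / (tp + fp + fn)
        vs = 1.0 - abs(fn - fp) / denom

    if tp + fn == 0:
        flags.append("fn_rate_undefined")
        fn_rate = float("nan")
    else:
        fn_rate = fn / (tp + fn)

    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    return float(dsc), float(jaccard), float(fn_rate), float(mcc), float(vs), flags


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background face-neighbour."""
    if mask.ndim == 3:
        structure = np.zeros((3, 3, 3), bool)
        structure[1, 1, :] = structure[1, :, 1] = structure[:, 1, 1] = True
    else:
        structure = np.zeros((3, 3), bool)
        structure[1, :] = structure[:, 1] = True
    eroded = binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def hd95(pred: np.ndarray, ref: np.ndarray,
         spacing: Optional[Sequence[float]] = None,
         variant: str = "pooled") -> float:
    """95th percentile of symmetric boundary surface distances.

    ``variant='pooled'`` (default) pools both directed distance sets before
    taking the percentile; ``variant='directed_mean'`` averages the two
    directed 95th percentiles.  Units are voxels unless ``spacing`` is given.
    """
    p = _binary(pred.voxels if isinstance(pred, SegmentationMask) else pred, "pred")
    r = _binary(ref.voxels if isinstance(ref, SegmentationMask) else ref, "ref")
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs ref {r.shape}")
    if not p.any() or not r.any():
        raise ValueError("hd95 undefined for an empty mask")
    if variant not in ("pooled", "directed_mean"):
        raise ValueError(f"unknown variant {variant!r}")

    bp, br = _boundary(p), _boundary(r)
    samp = None if spacing is None else tuple(spacing)
    # distance of every voxel to the nearest boundary voxel of the other mask
    dt_to_r = distance_transform_edt(~br, sampling=samp)
    dt_to_p = distance_transform_edt(~bp, sampling=samp)
    d_pr = dt_to_r[bp]
    d_rp = dt_to_p[br]
    if variant == "pooled":
        return float(np.percentile(np.concatenate([d_pr, d_rp]), 95))
    return float((np.percentile(d_pr, 95) + np.percentile(d_rp, 95)) / 2.0)


def roc_auc(prob: np.ndarray, ref: np.ndarray) -> float:
    """Voxelwise ROC area via the tie-averaged rank statistic."""
    prob = np.asarray(prob, dtype=np.float64).ravel()
    r = _binary(ref.voxels if isinstance(ref, SegmentationMask) else ref,
                "ref").ravel()
    if prob.shape != r.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs ref {r.shape}")
    npos = int(r.sum())
    nneg = r.size - npos
    if npos == 0 or nneg == 0:
        raise ValueError("roc_auc undefined for a single-class reference")
    ranks = rankdata(prob)
    return float((ranks[r].sum() - npos * (npos + 1) / 2.0) / (npos * nneg))


def evaluate_pair(pred: SegmentationMask, ref: SegmentationMask,
                  prob: Optional[np.ndarray] = None,
                  frames: Optional[Sequence[int]] = None,
                  use_spacing: bool = False) -> MetricReport:
    """Full panel for one scan.

    ``frames`` restricts the voxel domain to the kept (non-blank) frames so
    that background-dominated metrics (MCC, AUC) are computed over a fixed,
    meaningful domain rather than the whole padded stack.
    """
    pv, rv = pred.voxels, ref.voxels
    if pv.shape != rv.shape:
        raise ValueError(f"shape mismatch: pred {pv.shape} vs ref {rv.shape}")
    if frames is not None:
        idx = np.asarray(list(frames), dtype=int)
        pv, rv = pv[:, :, idx], rv[:, :, idx]
        prob_v = None if prob is None else prob[:, :, idx]
    else:
        prob_v = prob

    tp, fp, fn, tn = confusion_counts(pv, rv)
    dsc, jac, fnr, mcc, vs, flags = overlap_metrics(tp, fp, fn, tn)

    if pv.any() and rv.any():
        h = hd95(pv, rv, spacing=pred.spacing if use_spacing else None)
    else:
        h = float("nan")
        flags.append("hd95_undefined")

    if prob_v is not None and 0 < rv.sum() < rv.size:
        auc = roc_auc(prob_v, rv)
    else:
        auc = float("nan")
        if prob_v is not None:
            flags.append("auc_undefined")
    return MetricReport(dsc=dsc, jaccard=jac, fn_rate=fnr, mcc=mcc, hd95=h,
                        vs=vs, auc=auc, tp=tp, fp=fp, fn=fn, tn=tn, flags=flags)


# ---------------------------------------------------------------------------
# Slice-decile Dice profile

@dataclass
class DecileProfile:
    dsc_by_decile: List[float]       # NaN where undefined
    slice_extent: Tuple[int, int]

    def as_row(self) -> Dict:
        row = {f"decile_{i + 1}": self.dsc_by_decile[i] for i in range(10)}
        row["z_start"], row["z_end"] = self.slice_extent
        return row


def slice_decile_dsc(pred: SegmentationMask, ref: SegmentationMask,
                     mode: str = "pooled") -> DecileProfile:
    """Dice within ten contiguous bins of the reference kidney's slice extent.

    The extent is [first, last] frame with reference foreground; frame ``i``
    falls in bin ``floor(10 * (i - z_start) / extent_length)``.  Per-bin Dice
    is pooled over the bin's frames (``mode='frame_mean'`` averages per-frame
    Dice instead).  A bin where both masks are empty is NaN.
    """
    pv, rv = pred.voxels, ref.voxels
    if pv.shape != rv.shape:
        raise ValueError(f"shape mismatch: pred {pv.shape} vs ref {rv.shape}")
    if mode not in ("pooled", "frame_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    fg_frames = np.flatnonzero(rv.sum(axis=(0, 1)))
    if fg_frames.size == 0:
        raise ValueError("reference mask is empty; decile profile undefined")
    z0, z1 = int(fg_frames[0]), int(fg_frames[-1])
    length = z1 - z0 + 1

    bins: List[List[int]] = [[] for _ in range(10)]
    for z in range(z0, z1 + 1):
        b = min(int(10 * (z - z0) / length), 9)
        bins[b].append(z)

    out: List[float] = []
    for frames in bins:
        if not frames:
            out.append(float("nan"))
            continue
        if mode == "pooled":
            tp = fp = fn = 0
            for z in frames:
                t, f_, n_, _ = confusion_counts(pv[:, :, z], rv[:, :, z])
                tp, fp, fn = tp + t, fp + f_, fn + n_
            out.append(float("nan") if 2 * tp + fp + fn == 0
                       else 2.0 * tp / (2 * tp + fp + fn))
        else:
            vals = []
            for z in frames:
                t, f_, n_, _ = confusion_counts(pv[:, :, z], rv[:, :, z])
                if 2 * t + f_ + n_ > 0:
                    vals.append(2.0 * t / (2 * t + f_ + n_))
            out.append(float(np.mean(vals)) if vals else float("nan"))
    return DecileProfile(dsc_by_decile=out, slice_extent=(z0, z1))


def summarize_reports(reports: Sequence[MetricReport]) -> Dict[str, Dict[str, float]]:
    """Mean +/- SD summary across scans for each metric in the panel."""
    out: Dict[str, Dict[str, float]] = {}
    for key in ("dsc", "jaccard", "fn_rate", "mcc", "hd95", "vs", "auc"):
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        out[key] = {"mean": float(vals.mean()) if vals.size else float("nan"),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                    "n": int(vals.size)}
    return out
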