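"""Stack standardization, blank-frame filtering, and 3-slice slab assembly.

The training pipeline uses two geometries: a storage/analysis geometry
(default 320x320, reached by centred zero-padding or centred cropping that
never discards kidney voxels) and a model geometry (default 256x256, reached
by bilinear resampling).  Predictions are mapped back to the storage geometry
by the inverse resampling, so volumetry is always performed at 320x320.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import List, Optional, Tuple, Union

import numpy as np
from skimage.transform import resize

from .types import SegmentationMask, UltrasoundStack


@dataclass
class PreprocessConfig:
    target_inplane: int = 320
    slab_size: int = 256
    nonzero_frame_threshold: float = 0.20
    slab_channels: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonzero_frame_threshold <= 1.0:
            raise ValueError(
                f"nonzero_frame_threshold must lie in [0, 1], got {self.nonzero_frame_threshold}")
        if self.slab_size > self.target_inplane:
            raise ValueError(
                f"slab_size ({self.slab_size}) must not exceed target_inplane "
                f"({self.target_inplane})")
        if self.slab_channels != 3:
            raise ValueError("slab_channels is fixed at 3 (z-1, z, z+1)")


def _axis_window(n: int, target: int, lo: Optional[int], hi: Optional[int]) -> int:
    """Start index of a centred crop window, shifted minimally to keep [lo, hi]."""
    start = (n - target) // 2
    if lo is not None:
        if hi - lo + 1 > target:
            raise ValueError(
                f"cannot crop axis of size {n} to {target}: mask foreground spans "
                f"{hi - lo + 1} voxels and would be truncated")
        start = min(max(start, hi + 1 - target), lo)
    return int(np.clip(start, 0, n - target))


def standardize_stack(
    stack: UltrasoundStack,
    cfg: PreprocessConfig,
    mask: Optional[SegmentationMask] = None,
) -> Union[UltrasoundStack, Tuple[UltrasoundStack, SegmentationMask]]:
    """Bring a stack (and its paired mask) to target_inplane x target_inplane x Z.

    Smaller frames are centred in a zero border; larger frames are
    centre-cropped.  When a mask is supplied, the crop window is shifted to
    keep every foreground voxel — if the kidney cannot fit, the operation is
    rejected rather than silently truncating it.
    """
    h, w, nz = stack.voxels.shape
    if h < 1 or w < 1:
        raise ValueError(f"in-plane dimensions must be >= 1, got {(h, w)}")
    t = cfg.target_inplane
    if mask is not None and mask.voxels.shape != stack.voxels.shape:
        raise ValueError(
            f"mask shape {mask.voxels.shape} does not match stack {stack.voxels.shape}")

    fg = np.argwhere(mask.voxels) if mask is not None and mask.voxels.any() else None

    def one_axis(arr_h: int, axis: int):
        if arr_h >= t:
            lo = hi = None
            if fg is not None:
                lo, hi = int(fg[:, axis].min()), int(fg[:, axis].max())
            start = _axis_window(arr_h, t, lo, hi)
            return ("crop", start)
        pad = (t - arr_h) // 2
        return ("pad", pad)

    ops = [one_axis(h, 0), one_axis(w, 1)]

    def apply(vol: np.ndarray) -> np.ndarray:
        out = vol
        for axis, (kind, k) in enumerate(ops):
            n = out.shape[axis]
            if kind == "crop":
                sl = [slice(None)] * 3
                sl[axis] = slice(k, k + t)
                out = out[tuple(sl)]
            else:
                before, after = k, t - n - k
                padw = [(0, 0)] * 3
                padw[axis] = (before, after)
                out = np.pad(out, padw, mode="constant")
        return out

    new_stack = UltrasoundStack(voxels=apply(stack.voxels), spacing=stack.spacing,
                                patient_id=stack.patient_id, side=stack.side,
                                scan_index=stack.scan_index)
    if mask is None:
        return new_stack
    new_mask = SegmentationMask(voxels=apply(mask.voxels), spacing=mask.spacing)
    if new_mask.foreground_count() != mask.foreground_count():
        raise ValueError("standardization would discard kidney foreground voxels")
    return new_stack, new_mask


def filter_blank_frames(stack: UltrasoundStack, cfg: PreprocessConfig) -> List[int]:
    """Indices of frames whose non-zero pixel fraction is >= the threshold.

    Tracked sweeps begin and end before the probe acquires data, leaving blank
    frames that would dominate training as pure background; they are dropped.
    The threshold is inclusive: a frame at exactly 20% is kept.
    """
    if stack.voxels.size == 0 or stack.n_frames == 0:
        raise ValueError("cannot filter an empty stack")
    h, w, nz = stack.voxels.shape
    frac = (stack.voxels != 0).sum(axis=(0, 1)) / float(h * w)
    return [int(i) for i in range(nz) if frac[i] >= cfg.nonzero_frame_threshold]


def make_slab(
    stack: UltrasoundStack,
    z: int,
    cfg: PreprocessConfig,
    mask: Optional[SegmentationMask] = None,
):
    """Build the 3-channel model input for frame ``z``.

    Channels are frames (z-1, z, z+1), clamped at the sweep boundaries, each
    bilinearly resampled from the storage geometry to slab_size.  A paired
    mask slice is resampled nearest-neighbour (stays strictly binary).
    Returns ``(slab, mask_slab)`` where ``mask_slab`` is None without a mask;
    ``upsample_prediction`` is the recorded inverse mapping.
    """
    h, w, nz = stack.voxels.shape
    if not 0 <= z < nz:
        raise ValueError(f"frame index {z} outside stack with {nz} frames")
    if (h, w) != (cfg.target_inplane, cfg.target_inplane):
        raise ValueError(
            f"stack must be standardized to {cfg.target_inplane}px before slabbing, "
            f"got in-plane {(h, w)}")
    s = cfg.slab_size
    idx = [max(z - 1, 0), z, min(z + 1, nz - 1)]
    chans = []
    for i in idx:
        fr = stack.voxels[:, :, i].astype(np.float32)
        if s != cfg.target_inplane:
            fr = resize(fr, (s, s), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
        chans.append(fr.astype(np.float32))
    slab = np.stack(chans, axis=0)

    mask_slab = None
    if mask is not None:
        ms = mask.voxels[:, :, z]
        if s != cfg.target_inplane:
            ms = resize(ms, (s, s), order=0, mode="edge",
                        anti_aliasing=False, preserve_range=True)
        mask_slab = (ms > 0.5).astype(np.uint8)
    return slab, mask_slab


def upsample_prediction(prob: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Inverse of the slab resampling: slab_size -> target_inplane, bilinear."""
    t = cfg.target_inplane
    if prob.shape == (t, t):
        return prob.astype(np.float32)
    return resize(prob.astype(np.float32), (t, t), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True).astype(np.float32)
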