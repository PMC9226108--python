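"""Core in-memory containers shared by every pipeline stage.

Conventions
-----------
A stack's voxel array has shape ``(H, W, Z)``: ``H`` is the axial depth
direction (away from the probe face), ``W`` the lateral direction, and ``Z``
the sweep direction — frame ``i`` is ``voxels[:, :, i]``.  ``spacing`` is
``(dx, dy, dz)`` in millimetres along those same axes.  Intensities are
8-bit B-mode exports in ``[0, 255]``; masks are strictly ``{0, 1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

Sides = ("left", "right")
Sources = ("reader1", "reader2", "ai", "mri", "ground_truth")


def _check_spacing(spacing: Tuple[float, float, float]) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three strictly positive values, got {spacing}")
    return spacing


@dataclass
class UltrasoundStack:
    """A tracker-aligned 3D B-mode stack for one kidney acquisition."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    patient_id: str = ""
    side: str = "left"
    scan_index: int = 1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack voxels must be 3D (H, W, Z), got shape {self.voxels.shape}")
        self.spacing = _check_spacing(self.spacing)
        if self.side not in Sides:
            raise ValueError(f"side must be one of {Sides}, got {self.side!r}")
        if self.scan_index not in (1, 2, 3):
            raise ValueError(f"scan_index must be 1, 2 or 3, got {self.scan_index}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[2]

    def frame(self, z: int) -> np.ndarray:
        return self.voxels[:, :, z]

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class SegmentationMask:
    """A binary kidney mask aligned voxel-for-voxel with a stack."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask voxels must be 3D (H, W, Z), got shape {self.voxels.shape}")
        uniq = np.unique(self.voxels)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask must be binary with values in {{0, 1}}, found {uniq[:10]}")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    def foreground_count(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class KidneyVolumeRecord:
    """One kidney volume measurement: patient, side, scan repetition, source."""

    patient_id: str
    side: str
    scan_index: int
    volume_mL: float
    source: str

    def __post_init__(self) -> None:
        if self.side not in Sides:
            raise ValueError(f"side must be one of {Sides}, got {self.side!r}")
        if self.scan_index not in (1, 2, 3):
            raise ValueError(f"scan_index must be 1, 2 or 3, got {self.scan_index}")
        if self.volume_mL < 0:
            raise ValueError(f"volume_mL must be non-negative, got {self.volume_mL}")
        if self.source not in Sources:
            raise ValueError(f"source must be one of {Sources}, got {self.source!r}")


@dataclass(frozen=True)
class PatientTKV:
    """Patient-level total kidney volume: left+right summed per scan, then averaged."""

    patient_id: str
    tkv_mL: float
    n_observations: int
    source: str

    def __post_init__(self) -> None:
        if self.tkv_mL < 0:
            raise ValueError(f"tkv_mL must be non-negative, got {self.tkv_mL}")
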