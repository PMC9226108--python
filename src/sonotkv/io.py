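"""NIfTI persistence for stacks and masks, and a minimal DICOM-series converter.

Stacks and masks are written as ``.nii.gz`` with a diagonal affine carrying the
voxel spacing, so a stack/mask pair produced together always shares its affine.
"""

from __future__ import annotations

import os
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .types import SegmentationMask, UltrasoundStack


def _affine(spacing: Tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_stack(stack: UltrasoundStack, path: str) -> None:
    img = nib.Nifti1Image(stack.voxels.astype(np.uint8), _affine(stack.spacing))
    img.header.set_zooms(stack.spacing)
    nib.save(img, path)


def save_mask(mask: SegmentationMask, path: str) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, path)


def _load(path: str):
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_stack(path: str, patient_id: str = "", side: str = "left",
               scan_index: int = 1) -> UltrasoundStack:
    data, spacing = _load(path)
    return UltrasoundStack(voxels=data, spacing=spacing, patient_id=patient_id,
                           side=side, scan_index=scan_index)


def load_mask(path: str) -> SegmentationMask:
    data, spacing = _load(path)
    return SegmentationMask(voxels=(data > 0).astype(np.uint8), spacing=spacing)


def dicom_series_to_stack(directory: str, patient_id: str = "",
                          side: str = "left", scan_index: int = 1,
                          out_nifti: Optional[str] = None) -> UltrasoundStack:
    """Convert a directory of single-frame DICOM files into a stack.

    Only the minimal tags are honoured: ``PixelSpacing`` for in-plane spacing,
    ``SpacingBetweenSlices`` (or ``SliceThickness``) for the sweep step, and
    ``InstanceNumber`` for frame ordering.  Optionally also writes the NIfTI.
    """
    import pydicom

    files = sorted(
        os.path.join(directory, f) for f in os.listdir(directory)
        if not f.startswith(".")
    )
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    frames = [d.pixel_array for d in datasets]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in series: {shapes}")
    d0 = datasets[0]
    px = getattr(d0, "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(d0, "SpacingBetweenSlices", getattr(d0, "SliceThickness", 1.0)))
    stack = UltrasoundStack(
        voxels=np.stack(frames, axis=2),
        spacing=(float(px[0]), float(px[1]), dz),
        patient_id=patient_id, side=side, scan_index=scan_index,
    )
    if out_nifti is not None:
        save_stack(stack, out_nifti)
    return stack
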