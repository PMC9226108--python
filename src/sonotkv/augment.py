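"""Training-set augmentation: in-plane rotation plus random elastic deformation.

Each sample is expanded to ``multiplier`` pairs: the untouched original
followed by independently drawn warps.  The same geometric transform is
applied to image (bilinear) and mask (nearest-neighbour), so masks remain
strictly binary.  Horizontal flip and additive Gaussian noise are available
but off by default — flipping degrades anatomy-specific left/right cues and
noise adds little on speckle-corrupted inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import resize


@dataclass
class AugmentConfig:
    rotation_range_deg: float = 15.0
    elastic_grid_spacing: int = 32     # control-grid pitch, px
    elastic_sigma: float = 4.0         # displacement scale at 256^2, px
    multiplier: int = 3                # total copies incl. the original
    enable_flip: bool = False
    enable_gaussian_noise: bool = False
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError(f"multiplier must be >= 1, got {self.multiplier}")
        if self.rotation_range_deg < 0:
            raise ValueError(
                f"rotation_range_deg must be >= 0, got {self.rotation_range_deg}")
        if self.elastic_sigma < 0:
            raise ValueError(f"elastic_sigma must be >= 0, got {self.elastic_sigma}")


def _elastic_field(shape: Tuple[int, int], spacing: int, sigma: float,
                   rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Smooth displacement field from a coarse control grid, bicubic-upsampled."""
    h, w = shape
    gh = max(h // spacing, 2) + 1
    gw = max(w // spacing, 2) + 1
    du = rng.normal(0.0, sigma, size=(gh, gw))
    dv = rng.normal(0.0, sigma, size=(gh, gw))
    du = resize(du, shape, order=3, mode="reflect", anti_aliasing=False)
    dv = resize(dv, shape, order=3, mode="reflect", anti_aliasing=False)
    return du, dv


def _warp_coords(shape: Tuple[int, int], angle_deg: float,
                 du: np.ndarray, dv: np.ndarray) -> np.ndarray:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    y0, x0 = yy - cy, xx - cx
    src_y = cy + c * y0 - s * x0 + du
    src_x = cx + s * y0 + c * x0 + dv
    return np.stack([src_y, src_x], axis=0)


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 cfg: AugmentConfig) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Expand one (image, mask) slab pair into ``cfg.multiplier`` pairs.

    The first returned pair is the untouched input.  Deterministic for a
    fixed ``cfg.seed``.  Images may be 2D or channel-first 3D (the same warp
    is applied to every channel).
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[-2:] != mask.shape[-2:]:
        raise ValueError(
            f"image and mask in-plane shapes differ: {image.shape} vs {mask.shape}")

    rng = np.random.default_rng(cfg.seed)
    out: List[Tuple[np.ndarray, np.ndarray]] = [(image.copy(), mask.copy())]
    shape = image.shape[-2:]

    for _ in range(cfg.multiplier - 1):
        angle = float(rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg))
        if cfg.elastic_sigma > 0:
            du, dv = _elastic_field(shape, cfg.elastic_grid_spacing,
                                    cfg.elastic_sigma, rng)
        else:
            du = dv = np.zeros(shape)
        coords = _warp_coords(shape, angle, du, dv)
        flip = bool(cfg.enable_flip and rng.random() < 0.5)

        def warp(arr: np.ndarray, order: int) -> np.ndarray:
            def one(frame: np.ndarray) -> np.ndarray:
                w = map_coordinates(frame.astype(np.float64), coords,
                                    order=order, mode="constant", cval=0.0)
                return w[:, ::-1] if flip else w
            if arr.ndim == 2:
                return one(arr)
            return np.stack([one(arr[c]) for c in range(arr.shape[0])], axis=0)

        aug_img = warp(image, order=1)
        aug_mask = (warp(mask, order=0) > 0.5).astype(mask.dtype)
        if cfg.enable_gaussian_noise:
            aug_img = aug_img + rng.normal(0.0, cfg.noise_sigma, size=aug_img.shape)
            aug_img = np.clip(aug_img, 0, 255)
        out.append((aug_img.astype(image.dtype if image.dtype.kind == "f"
                                   else np.float32), aug_mask))
    return out
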