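"""Synthetic tracker-aligned 3D ultrasound kidney phantoms with analytic truth.

The generator emulates the acquisition variability of a freehand B-mode sweep
over a polycystic kidney: a fan-shaped sector field of view replicated along
the sweep axis, per-patient gain differences, depth attenuation, multiplicative
speckle, hypoechoic cysts inside a bright-rimmed ellipsoidal kidney, and blank
frames at the start and end of the sweep where the probe is not yet acquiring.

Every stack comes with the exact voxel-aligned ground-truth mask and the
analytic kidney volume, so segmentation, volumetry and agreement statistics
can all be validated without patient data.

Geometry: in-plane rows are axial depth (away from the probe), columns are
lateral, and the third axis is the sweep.  All physical quantities are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .types import SegmentationMask, UltrasoundStack

GAIN_RANGE = (0.54, 0.68)  # clinical per-patient image-gain span emulated here

DIFFICULTIES = ("centered", "small_fov", "low_contrast", "oversized")

_ALLOWED_INPLANE = (64, 128, 256, 512)


@dataclass
class PhantomSpec:
    """Complete description of one phantom kidney acquisition.

    ``semi_axes`` are the kidney's ellipsoid semi-axes (depth, lateral, sweep);
    ``center`` is the kidney centre as an offset from the sector's mid-depth
    point; ``cysts`` are spheres given in the kidney's local (unrotated) frame
    so they travel with the kidney under orientation jitter.
    """

    semi_axes: Tuple[float, float, float] = (26.0, 32.0, 31.0)
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    cysts: Sequence[Tuple[Tuple[float, float, float], float]] = ()
    sector_apex: Tuple[float, float] = (2.0, 0.0)   # (depth above frame top, lateral) mm
    sector_width_deg: float = 72.0
    sector_depth: float = 140.0
    gain: float = 0.61
    speckle_scale: float = 0.35
    attenuation_coeff: float = 0.004                # per-mm intensity decay
    in_plane_size: int = 128
    n_frames: int = 48
    spacing: Tuple[float, float, float] = (1.2, 1.2, 2.2)
    blank_margin: float = 0.08                      # fraction of frames blank per sweep end
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError(f"semi-axes must be strictly positive, got {self.semi_axes}")
        for c, r in self.cysts:
            if r <= 0:
                raise ValueError(f"cyst radius must be strictly positive, got {r}")
        if not 0.0 <= self.gain <= 1.0:
            raise ValueError(f"gain must lie in [0, 1], got {self.gain}")
        if self.n_frames < 3:
            raise ValueError(f"n_frames must be >= 3, got {self.n_frames}")
        if self.in_plane_size not in _ALLOWED_INPLANE:
            raise ValueError(
                f"in_plane_size must be one of {_ALLOWED_INPLANE}, got {self.in_plane_size}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not 0.0 <= self.blank_margin < 0.5:
            raise ValueError(f"blank_margin must lie in [0, 0.5), got {self.blank_margin}")


# ---------------------------------------------------------------------------
# Spec sampling

def sample_spec(seed: int, difficulty: str = "centered",
                scale: str = "desk") -> PhantomSpec:
    """Draw a reproducible phantom spec for one of the acquisition scenarios.

    ``difficulty`` mirrors the challenges seen in clinical sweeps: a kidney
    neatly centred in the sector, a sector too narrow for comfort, a
    low-gain/high-speckle acquisition, and a kidney too large for the field
    of view (whose ground truth is therefore clipped by the sector).
    ``scale`` selects the grid: ``desk`` (128-px, 48 frames) for CPU-sized
    work, ``full`` (256-px, 320 frames) matching clinical stack geometry.
    """
    if seed < 0:
        raise ValueError(f"seed must be a non-negative integer, got {seed}")
    if difficulty not in DIFFICULTIES:
        raise ValueError(
            f"unknown difficulty {difficulty!r}; expected one of {DIFFICULTIES}")
    if scale not in ("desk", "full"):
        raise ValueError(f"scale must be 'desk' or 'full', got {scale!r}")

    rng = np.random.default_rng([int(seed), DIFFICULTIES.index(difficulty)])

    if scale == "desk":
        in_plane, n_frames, spacing = 128, 48, (1.2, 1.2, 2.2)
    else:
        in_plane, n_frames, spacing = 256, 320, (0.7, 0.7, 0.42)

    height_mm = in_plane * spacing[0]
    depth = float(rng.uniform(0.80, 0.92)) * height_mm
    width = float(rng.uniform(66.0, 80.0))
    apex = (2.0, float(rng.uniform(-4.0, 4.0)))

    gain = float(rng.uniform(*GAIN_RANGE))
    speckle = float(rng.uniform(0.25, 0.40))

    axes = np.array([rng.uniform(20.0, 30.0),
                     rng.uniform(24.0, 36.0),
                     rng.uniform(26.0, 36.0)])
    size_factor = float(rng.uniform(0.9, 1.6))
    center = np.array([rng.uniform(-6.0, 6.0),
                       rng.uniform(-5.0, 5.0),
                       rng.uniform(-3.0, 3.0)])
    orient = rng.uniform(-20.0, 20.0, size=3)

    if difficulty == "small_fov":
        width = float(rng.uniform(52.0, 60.0))
        depth = 0.72 * height_mm
    elif difficulty == "low_contrast":
        gain = float(rng.uniform(0.54, 0.57))
        speckle = float(rng.uniform(0.45, 0.60))
    elif difficulty == "oversized":
        # long axis exceeds the sector depth, forcing FOV clipping of the truth
        size_factor = float(rng.uniform(1.0, 1.15)) * depth / (2.0 * axes.max())
        size_factor *= float(rng.uniform(1.05, 1.20))
        center[0] = float(rng.uniform(-2.0, 2.0))

    axes = axes * size_factor

    cysts = _sample_cysts(rng, axes)

    return PhantomSpec(
        semi_axes=tuple(float(a) for a in axes),
        center=tuple(float(c) for c in center),
        orientation_deg=tuple(float(o) for o in orient),
        cysts=cysts,
        sector_apex=apex,
        sector_width_deg=width,
        sector_depth=depth,
        gain=gain,
        speckle_scale=speckle,
        attenuation_coeff=0.004,
        in_plane_size=in_plane,
        n_frames=n_frames,
        spacing=spacing,
        seed=int(seed),
    )


def _sample_cysts(rng: np.random.Generator,
                  axes: np.ndarray) -> List[Tuple[Tuple[float, float, float], float]]:
    """Sample 2-6 cysts strictly interior to the ellipsoid (local frame)."""
    n = int(rng.integers(2, 7))
    amin = float(axes.min())
    out: List[Tuple[Tuple[float, float, float], float]] = []
    for _ in range(n):
        for _attempt in range(40):
            r = float(rng.uniform(0.12, 0.30)) * amin
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = float(rng.uniform(0.0, 1.0)) ** (1 / 3)
            q = u * rad * (axes - r) * 0.9
            # conservative interiority: scaled distance plus scaled radius
            if np.linalg.norm(q / axes) + r / amin <= 0.95:
                out.append(((float(q[0]), float(q[1]), float(q[2])), r))
                break
    return out


# ---------------------------------------------------------------------------
# Rendering

def _grid_coords(spec: PhantomSpec):
    """Physical (x depth, y lateral, z sweep) coordinates of voxel centres."""
    h = w = spec.in_plane_size
    dx, dy, dz = spec.spacing
    x = np.arange(h) * dx
    y = (np.arange(w) - (w - 1) / 2.0) * dy
    z = (np.arange(spec.n_frames) - (spec.n_frames - 1) / 2.0) * dz
    return x, y, z


def _sector_mask_2d(spec: PhantomSpec) -> np.ndarray:
    x, y, _ = _grid_coords(spec)
    ax, ay = spec.sector_apex
    X = x[:, None] + ax            # depth from apex
    Y = y[None, :] - ay
    r = np.hypot(X, Y)
    ang = np.degrees(np.arctan2(Y, X))
    half = spec.sector_width_deg / 2.0
    return (X >= 0) & (r <= spec.sector_depth) & (np.abs(ang) <= half)


def _sweep_coverage(spec: PhantomSpec) -> np.ndarray:
    """Boolean per-frame flag: True where the probe was acquiring."""
    margin = int(round(spec.blank_margin * spec.n_frames))
    cov = np.zeros(spec.n_frames, dtype=bool)
    cov[margin:spec.n_frames - margin] = True
    return cov


def fov_mask(spec: PhantomSpec) -> np.ndarray:
    """Full 3D field-of-view support: sector in-plane x sweep coverage."""
    sector = _sector_mask_2d(spec)
    cov = _sweep_coverage(spec)
    return sector[:, :, None] & cov[None, None, :]


def _kidney_center_physical(spec: PhantomSpec) -> np.ndarray:
    ax, ay = spec.sector_apex
    mid_depth = 0.55 * spec.sector_depth - ax
    return np.array([mid_depth, ay, 0.0]) + np.asarray(spec.center, dtype=float)


def _local_coords(spec: PhantomSpec) -> np.ndarray:
    """Map the voxel grid into the kidney's local frame; shape (H, W, Z, 3)."""
    x, y, z = _grid_coords(spec)
    c = _kidney_center_physical(spec)
    rot = Rotation.from_euler("zyx", spec.orientation_deg, degrees=True)
    Rm = rot.as_matrix()
    X, Y, Z = np.meshgrid(x - c[0], y - c[1], z - c[2], indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    return pts @ Rm  # rows of Rm.T applied: world -> local


def _kidney_fields(spec: PhantomSpec):
    """Scaled ellipsoid distance and cyst membership on the voxel grid."""
    loc = _local_coords(spec)
    axes = np.asarray(spec.semi_axes, dtype=float)
    d = np.linalg.norm(loc / axes, axis=-1)
    in_cyst = np.zeros(d.shape, dtype=bool)
    for (q, r) in spec.cysts:
        in_cyst |= np.linalg.norm(loc - np.asarray(q, dtype=float), axis=-1) <= r
    return d, in_cyst


def kidney_support(spec: PhantomSpec) -> np.ndarray:
    """Voxelized kidney (ellipsoid union cysts) with no field-of-view clipping."""
    d, in_cyst = _kidney_fields(spec)
    return (d <= 1.0) | in_cyst


def analytic_kidney_volume_mL(spec: PhantomSpec) -> float:
    """Exact (FOV-unclipped) kidney volume: ellipsoid plus protruding cysts.

    Cysts fully interior to the ellipsoid contribute nothing to the union.
    A protruding cyst's extra volume has no closed form against an ellipsoid,
    so it is evaluated by deterministic grid quadrature at 0.25 mm.
    """
    a, b, c = spec.semi_axes
    vol = 4.0 / 3.0 * np.pi * a * b * c
    axes = np.asarray(spec.semi_axes, dtype=float)
    amin = float(axes.min())
    for (q, r) in spec.cysts:
        q = np.asarray(q, dtype=float)
        if np.linalg.norm(q / axes) + r / amin <= 1.0:
            continue  # provably interior
        step = 0.25
        g = np.arange(-r, r + step, step)
        X, Y, Z = np.meshgrid(q[0] + g, q[1] + g, q[2] + g, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        in_sphere = np.linalg.norm(pts - q, axis=-1) <= r
        in_ell = np.linalg.norm(pts / axes, axis=-1) <= 1.0
        vol += float((in_sphere & ~in_ell).sum()) * step ** 3
    return vol / 1000.0


_TISSUE, _PARENCHYMA, _RIM, _CYST = 0.50, 0.28, 0.88, 0.05
_RIM_BAND = (0.90, 1.10)  # shell of the scaled ellipsoid distance


def render_phantom(spec: PhantomSpec,
                   patient_id: str = "PHANTOM",
                   side: str = "left",
                   scan_index: int = 1,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[UltrasoundStack, SegmentationMask, float]:
    """Render one phantom acquisition.

    Returns the B-mode stack, the ground-truth mask (kidney union cysts,
    clipped to the field of view — cysts are hypoechoic but are kidney), and
    the analytic unclipped kidney volume in mL.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    d, in_cyst = _kidney_fields(spec)
    fov = fov_mask(spec)

    kidney = (d <= 1.0) | in_cyst
    mask = (kidney & fov).astype(np.uint8)

    template = np.full(d.shape, _TISSUE, dtype=np.float64)
    template[d <= 1.0] = _PARENCHYMA
    template[in_cyst] = _CYST
    rim = (d >= _RIM_BAND[0]) & (d <= _RIM_BAND[1])
    template[rim] = _RIM
    template = gaussian_filter(template, sigma=(1.0, 1.0, 0.5))

    x, _, _ = _grid_coords(spec)
    depth_from_apex = x + spec.sector_apex[0]
    atten = np.exp(-spec.attenuation_coeff * np.clip(depth_from_apex, 0, None))
    img = template * atten[:, None, None] * (spec.gain * 1.9)

    if spec.speckle_scale > 0:
        # first-order B-mode speckle: multiplicative Rayleigh with unit mean
        ray = rng.rayleigh(scale=np.sqrt(2 / np.pi), size=img.shape)
        img = img * (1.0 + spec.speckle_scale * (ray - 1.0))

    img = np.where(fov, img, 0.0)
    img = np.clip(img * 255.0, 0, 255).astype(np.uint8)
    # keep FOV support exact after quantization: interior voxels are >= 1
    img[fov & (img == 0)] = 1

    stack = UltrasoundStack(voxels=img, spacing=spec.spacing,
                            patient_id=patient_id, side=side,
                            scan_index=scan_index)
    gt = SegmentationMask(voxels=mask, spacing=spec.spacing)
    return stack, gt, analytic_kidney_volume_mL(spec)


def render_scan_triple(spec: PhantomSpec, jitter_seed: int,
                       patient_id: str = "PHANTOM", side: str = "left",
                       orientation_jitter_deg: float = 6.0,
                       gain_jitter: float = 0.02,
                       shift_jitter_mm: float = 3.0
                       ) -> List[Tuple[UltrasoundStack, SegmentationMask]]:
    """Render three sweeps of the same kidney with acquisition jitter.

    The kidney itself is unchanged; orientation, gain and probe placement are
    perturbed per sweep, so the three ground-truth masks differ only through
    re-voxelization and field-of-view clipping — exactly the situation the
    interscan-variability statistic quantifies.
    """
    from dataclasses import replace

    rng = np.random.default_rng([int(jitter_seed), spec.seed])
    out = []
    for k in range(3):
        dor = rng.uniform(-orientation_jitter_deg, orientation_jitter_deg, size=3)
        dg = float(rng.uniform(-gain_jitter, gain_jitter))
        dsh = rng.uniform(-shift_jitter_mm, shift_jitter_mm, size=3)
        jittered = replace(
            spec,
            orientation_deg=tuple(float(v) for v in np.asarray(spec.orientation_deg) + dor),
            gain=float(np.clip(spec.gain + dg, 0.0, 1.0)),
            center=tuple(float(v) for v in np.asarray(spec.center) + dsh),
        )
        # speckle seeded from the jittered geometry itself: identical jitter
        # (e.g. all amplitudes zero) reproduces bit-identical sweeps
        speckle_seed = _content_seed(jittered, jitter_seed)
        stack, mask, _ = render_phantom(
            jittered, patient_id=patient_id, side=side, scan_index=k + 1,
            rng=np.random.default_rng(speckle_seed))
        out.append((stack, mask))
    return out


def _content_seed(spec: PhantomSpec, salt: int) -> int:
    """Stable 31-bit seed derived from a spec's numeric content."""
    import zlib

    payload = repr((spec.semi_axes, spec.center, spec.orientation_deg,
                    tuple(spec.cysts), spec.sector_apex, spec.sector_width_deg,
                    spec.sector_depth, round(spec.gain, 9), spec.speckle_scale,
                    spec.seed, int(salt))).encode()
    return zlib.crc32(payload) & 0x7FFFFFFF
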