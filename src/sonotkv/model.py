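"""The 2D U-Net segmentation model: architecture, Dice loss, training, prediction.

The network follows the encoder-decoder U-Net pattern with six resolution
levels at full scale: one conv-BN-ReLU block per level, encoder filters
doubling 32 -> 1024, a kernel-size schedule running (7,7) -> (5,5) -> (3,3)
at the base and mirrored back up the decoder, 2x2 learned up-convolutions
with skip concatenation, and a sigmoid 1x1 head.  Training minimises the
soft Dice loss with Adam.  Slab inputs are 3 consecutive frames (z-1, z, z+1)
— a 2.5D convention that gives the 2D network through-plane context.

A reduced-width configuration (``desk_unet_config``) trains in minutes on one
CPU and is used throughout the phantom experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .preprocess import PreprocessConfig, filter_blank_frames, make_slab, upsample_prediction
from .types import SegmentationMask, UltrasoundStack


@dataclass
class UNetConfig:
    levels: int = 6
    base_filters: int = 32
    max_filters: int = 1024
    kernel_schedule: Optional[Sequence[int]] = None  # per level, encoder order
    slab_size: int = 256
    learning_rate: float = 1e-6
    epochs: int = 200
    batch_size: int = 8
    loss: str = "dice"
    pretrained_weights_path: Optional[str] = None
    binarize_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError(f"need at least 2 levels, got {self.levels}")
        if self.loss != "dice":
            raise ValueError(f"only the Dice loss is supported, got {self.loss!r}")
        if self.kernel_schedule is None:
            self.kernel_schedule = ([7, 7, 5, 5, 3, 3] if self.levels == 6
                                    else [3] * self.levels)
        self.kernel_schedule = list(self.kernel_schedule)
        if len(self.kernel_schedule) != self.levels:
            raise ValueError(
                f"kernel_schedule length {len(self.kernel_schedule)} != levels {self.levels}")

    def filters(self) -> List[int]:
        return [min(self.base_filters * 2 ** i, self.max_filters)
                for i in range(self.levels)]


def desk_unet_config(**overrides) -> UNetConfig:
    """Reduced-width configuration for CPU-scale phantom experiments."""
    kw = dict(levels=4, base_filters=8, max_filters=64, slab_size=64,
              learning_rate=3e-3, epochs=12, batch_size=8)
    kw.update(overrides)
    return UNetConfig(**kw)


class UNet:
    """Numpy U-Net with explicit skip connections; built by :func:`build_unet`."""

    def __init__(self, cfg: UNetConfig):
        L = cfg.levels
        if cfg.slab_size % (2 ** (L - 1)) != 0:
            raise ValueError(
                f"slab size {cfg.slab_size} is not divisible by 2^(levels-1) "
                f"= {2 ** (L - 1)}; pooling would not be reversible")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.filters()
        ks = cfg.kernel_schedule

        def block(cin, cout, k):
            return [nn.Conv2d(cin, cout, k, rng), nn.BatchNorm2d(cout), nn.ReLU()]

        self.enc = [block(3 if i == 0 else f[i - 1], f[i], ks[i]) for i in range(L)]
        self.pools = [nn.MaxPool2d() for _ in range(L - 1)]
        self.ups = [nn.UpConv2d(f[i + 1], f[i], rng) for i in range(L - 2, -1, -1)]
        self.dec = [block(2 * f[i], f[i], ks[i]) for i in range(L - 2, -1, -1)]
        self.final = nn.Conv2d(f[0], 1, 1, rng)
        self._layers: List[nn.Layer] = (
            [l for b in self.enc for l in b] + self.pools + self.ups
            + [l for b in self.dec for l in b] + [self.final])

    # -- plumbing -----------------------------------------------------------
    def params(self) -> List[nn.Param]:
        return [p for layer in self._layers for p in layer.params()]

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def summary(self) -> Dict:
        cfg = self.cfg
        return {
            "levels": cfg.levels,
            "encoder_filters": cfg.filters(),
            "kernel_schedule_encoder": list(cfg.kernel_schedule),
            "kernel_schedule_decoder": list(cfg.kernel_schedule[:-1][::-1]),
            "slab_size": cfg.slab_size,
            "final_activation": "sigmoid",
            "batch_size": cfg.batch_size,
            "padding": "zero (same)",
            "normalization": "batch norm per level",
            "optimizer": "adam",
            "parameter_count": self.param_count(),
        }

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 3, S, S) float32 in [0, 1] -> probabilities (N, 1, S, S)."""
        L = self.cfg.levels
        skips = []
        h = x.astype(np.float32)
        for i in range(L):
            for layer in self.enc[i]:
                h = layer.forward(h, train)
            if i < L - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        for j in range(L - 1):
            h = self.ups[j].forward(h, train)
            skip = skips[L - 2 - j]
            h = np.concatenate([skip, h], axis=1)
            for layer in self.dec[j]:
                h = layer.forward(h, train)
        logits = self.final.forward(h, train)
        prob = nn.sigmoid(logits)
        if train:
            self._prob = prob
            self._nskip = [s.shape[1] for s in skips]
        return prob

    def backward(self, dprob: np.ndarray) -> None:
        L = self.cfg.levels
        prob = self._prob
        d = (dprob * prob * (1.0 - prob)).astype(np.float32)
        d = self.final.backward(d)
        dskips: List[Optional[np.ndarray]] = [None] * (L - 1)
        for j in range(L - 2, -1, -1):
            for layer in reversed(self.dec[j]):
                d = layer.backward(d)
            nskip = self._nskip[L - 2 - j]
            dskips[L - 2 - j] = d[:, :nskip]
            d = self.ups[j].backward(d[:, nskip:])
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            for layer in reversed(self.enc[i]):
                d = layer.backward(d)
        self._prob = None

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> List[np.ndarray]:
        arrs = [p.value for p in self.params()]
        for layer in self._layers:
            if isinstance(layer, nn.BatchNorm2d):
                arrs += [layer.running_mean, layer.running_var]
        return arrs

    def set_state(self, arrs: Sequence[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrs[:len(ps)]):
            if p.value.shape != a.shape:
                raise ValueError(
                    f"weight shape mismatch: expected {p.value.shape}, got {a.shape}")
            p.value = a.astype(np.float32).copy()
        rest = list(arrs[len(ps):])
        for layer in self._layers:
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = rest.pop(0).astype(np.float32).copy()
                layer.running_var = rest.pop(0).astype(np.float32).copy()

    def save_weights(self, path: str) -> None:
        arrs = self.state_arrays()
        np.savez_compressed(path, arch=json.dumps(self.summary()),
                            **{f"w{i}": a for i, a in enumerate(arrs)})

    def load_weights(self, path: str) -> None:
        with np.load(path, allow_pickle=False) as z:
            n = len([k for k in z.files if k.startswith("w")])
            self.set_state([z[f"w{i}"] for i in range(n)])


def build_unet(cfg: UNetConfig) -> Tuple[UNet, Dict]:
    """Construct the network; returns (model, architecture summary).

    If ``cfg.pretrained_weights_path`` is set, weights are loaded from it
    (the transfer-learning hook: a checkpoint from a source-domain model with
    the same architecture initialises training on ultrasound slabs).
    """
    model = UNet(cfg)
    if cfg.pretrained_weights_path:
        model.load_weights(cfg.pretrained_weights_path)
    return model, model.summary()


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-6) -> float:
    """1 - soft Dice overlap; 0 for perfect agreement, ~1 for disjoint masks."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    dice, _ = nn.soft_dice(pred, target, eps)
    return float(1.0 - dice)


# ---------------------------------------------------------------------------
# Training

@dataclass
class SlabDataset:
    """Model-ready slabs: images (N,3,S,S) at 0-255 scale, binary masks (N,S,S)."""

    images: np.ndarray
    masks: np.ndarray
    patient_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.masks = np.asarray(self.masks)
        if len(self.images) != len(self.masks):
            raise ValueError("images and masks lengths differ")
        if self.patient_ids and len(self.patient_ids) != len(self.images):
            raise ValueError("patient_ids length differs from images")

    def __len__(self) -> int:
        return len(self.images)


def _hard_dice(model: UNet, ds: SlabDataset, batch: int, thr: float) -> float:
    """Pooled binary Dice of thresholded predictions over a whole dataset."""
    inter = psum = tsum = 0.0
    for i in range(0, len(ds), batch):
        x = ds.images[i:i + batch] / 255.0
        prob = model.forward(x, train=False)[:, 0]
        p = prob >= thr
        t = ds.masks[i:i + batch] > 0
        inter += float((p & t).sum())
        psum += float(p.sum())
        tsum += float(t.sum())
    return (2.0 * inter + 1e-6) / (psum + tsum + 1e-6)


def train(model: UNet, train_ds: SlabDataset, val_ds: Optional[SlabDataset],
          cfg: UNetConfig, verbose: bool = False) -> Tuple[UNet, List[Dict]]:
    """Train with Adam on the Dice loss; keep the best-validation checkpoint.

    Partitions must be disjoint at the patient level — the same patient's
    scans appearing in both train and validation leaks anatomy and is
    rejected outright.
    """
    if len(train_ds) == 0:
        raise ValueError("training set is empty")
    if val_ds is not None and train_ds.patient_ids and val_ds.patient_ids:
        overlap = set(train_ds.patient_ids) & set(val_ds.patient_ids)
        if overlap:
            raise ValueError(
                f"patient-level overlap between train and validation: {sorted(overlap)}")

    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    history: List[Dict] = []
    best_val = -1.0
    best_state: Optional[List[np.ndarray]] = None

    n = len(train_ds)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        dices, losses = [], []
        for i in range(0, n, cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            x = train_ds.images[sel] / 255.0
            t = (train_ds.masks[sel] > 0).astype(np.float32)[:, None]
            opt.zero_grad()
            prob = model.forward(x, train=True)
            dice, grad = nn.soft_dice(prob, t)
            model.backward(-grad)  # minimize 1 - dice
            opt.step()
            dices.append(dice)
            losses.append(1.0 - dice)
        row = {"epoch": epoch + 1,
               "train_dice": float(np.mean(dices)),
               "loss": float(np.mean(losses)),
               "val_dice": float("nan")}
        if val_ds is not None and len(val_ds):
            row["val_dice"] = _hard_dice(model, val_ds, cfg.batch_size,
                                         cfg.binarize_threshold)
            if row["val_dice"] > best_val:
                best_val = row["val_dice"]
                best_state = [a.copy() for a in model.state_arrays()]
        history.append(row)
        if verbose:
            print(f"epoch {row['epoch']:3d}  train_dice {row['train_dice']:.4f}"
                  f"  val_dice {row['val_dice']:.4f}")
    if best_state is not None:
        model.set_state(best_state)
    return model, history


def save_history_csv(history: List[Dict], path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=["epoch", "train_dice", "val_dice", "loss"])
        wr.writeheader()
        for row in history:
            wr.writerow({k: row[k] for k in wr.fieldnames})


# ---------------------------------------------------------------------------
# Prediction

def predict_stack(model: UNet, stack: UltrasoundStack, pre_cfg: PreprocessConfig,
                  ) -> Tuple[np.ndarray, SegmentationMask]:
    """Segment every kept frame of a standardized stack.

    Returns the probability volume in the storage geometry (zero on frames
    removed by the blank-frame filter) and the thresholded mask.
    """
    cfg = model.cfg
    if pre_cfg.slab_size != cfg.slab_size:
        raise ValueError(
            f"geometry mismatch: preprocess slab {pre_cfg.slab_size} vs model "
            f"slab {cfg.slab_size}")
    h, w, nz = stack.voxels.shape
    t = pre_cfg.target_inplane
    if (h, w) != (t, t):
        raise ValueError(
            f"stack must be standardized to {t}px in-plane, got {(h, w)}")

    kept = filter_blank_frames(stack, pre_cfg)
    prob_vol = np.zeros((t, t, nz), dtype=np.float32)
    batch = max(cfg.batch_size, 1)
    for i in range(0, len(kept), batch):
        zs = kept[i:i + batch]
        slabs = np.stack([make_slab(stack, z, pre_cfg)[0] for z in zs]) / 255.0
        probs = model.forward(slabs.astype(np.float32), train=False)[:, 0]
        for z, p in zip(zs, probs):
            prob_vol[:, :, z] = upsample_prediction(p, pre_cfg)
    mask = np.zeros_like(prob_vol, dtype=np.uint8)
    if kept:
        kept_arr = np.array(kept)
        mask[:, :, kept_arr] = (
            prob_vol[:, :, kept_arr] >= cfg.binarize_threshold).astype(np.uint8)
    return prob_vol, SegmentationMask(voxels=mask, spacing=stack.spacing)
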