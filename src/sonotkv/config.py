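"""Experiment configuration and patient-level dataset splitting."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .augment import AugmentConfig
from .model import UNetConfig, desk_unet_config
from .preprocess import PreprocessConfig


def scaled_ratio(n: int, base: Tuple[int, int, int] = (15, 2, 5)
                 ) -> Tuple[int, int, int]:
    """Scale a (train, val, test) patient ratio to a cohort of size ``n``.

    Largest-remainder apportionment; every nonzero base part keeps at least
    one patient.  ``scaled_ratio(22)`` is (15, 2, 5) itself and
    ``scaled_ratio(12)`` gives (8, 1, 3).
    """
    base = tuple(int(b) for b in base)
    if n < sum(1 for b in base if b > 0):
        raise ValueError(f"cohort of {n} too small for ratio {base}")
    total = sum(base)
    exact = [n * b / total for b in base]
    parts = [int(np.floor(e)) for e in exact]
    for i, b in enumerate(base):
        if b > 0 and parts[i] == 0:
            parts[i] = 1
    while sum(parts) > n:
        i = int(np.argmax(parts))
        parts[i] -= 1
    rema = [e - p for e, p in zip(exact, parts)]
    while sum(parts) < n:
        i = int(np.argmax(rema))
        parts[i] += 1
        rema[i] = -1.0
    return tuple(parts)


def split_cohort(patient_ids: Sequence[str],
                 ratio: Tuple[int, int, int],
                 seed: int) -> Tuple[List[str], List[str], List[str]]:
    """Random patient-level split into disjoint (train, val, test) lists.

    Scans of one patient never cross partitions because the unit of
    assignment is the patient.  Deterministic under ``seed``.  Patients
    beyond ``sum(ratio)`` are left unassigned (returned in none of the
    lists); a ratio exceeding the cohort is rejected.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient_ids contains duplicates")
    ntr, nva, nte = (int(r) for r in ratio)
    if min(ntr, nva, nte) < 0:
        raise ValueError(f"ratio parts must be non-negative, got {ratio}")
    if ntr + nva + nte > len(ids):
        raise ValueError(
            f"ratio {ratio} requires {ntr + nva + nte} patients, cohort has {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    train = sorted(order[:ntr])
    val = sorted(order[ntr:ntr + nva])
    test = sorted(order[ntr + nva:ntr + nva + nte])
    assert not (set(train) & set(val) or set(train) & set(test) or set(val) & set(test))
    return train, val, test


@dataclass
class ExperimentConfig:
    """End-to-end phantom experiment: simulate -> train -> evaluate -> classify."""

    n_patients: int = 12
    split_basis: Tuple[int, int, int] = (15, 2, 5)
    seed: int = 0
    difficulty_mix: Tuple[str, ...] = ("centered", "small_fov", "low_contrast", "oversized")
    scale: str = "desk"
    max_train_slabs: int = 480
    out_dir: Optional[str] = None
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(target_inplane=128, slab_size=64))
    augment: AugmentConfig = field(
        default_factory=lambda: AugmentConfig(multiplier=1))
    model: UNetConfig = field(default_factory=desk_unet_config)

    def ratio(self) -> Tuple[int, int, int]:
        return scaled_ratio(self.n_patients, self.split_basis)

    def as_dict(self) -> Dict:
        d = asdict(self)
        d["ratio"] = list(self.ratio())
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_experiment_config(path: str) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file with nested sub-configs."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "preprocess" in kwargs:
        kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
    if "augment" in kwargs:
        kwargs["augment"] = AugmentConfig(**kwargs["augment"])
    if "model" in kwargs:
        kwargs["model"] = UNetConfig(**kwargs["model"])
    for tup_key in ("split_basis", "difficulty_mix"):
        if tup_key in kwargs and isinstance(kwargs[tup_key], list):
            kwargs[tup_key] = tuple(kwargs[tup_key])
    return ExperimentConfig(**kwargs)
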