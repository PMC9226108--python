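"""The end-to-end phantom experiment: the desk-scale analogue of a full study.

Simulates a fleet of phantom patients (two kidneys, three tracked sweeps
each), splits them at the patient level, trains the reduced-width U-Net on
the training patients' slabs, predicts the held-out test sweeps, and runs the
complete downstream analysis: per-scan metric panel, slice-decile profiles,
volumetry with interscan variability, volume agreement statistics, and
severity classification of AI-measured against ground-truth TKV.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .agreement import compare_methods
from .augment import augment_pair
from .classify import classify_cohort
from .config import ExperimentConfig, split_cohort
from .metrics import evaluate_pair, slice_decile_dsc, summarize_reports
from .model import SlabDataset, build_unet, predict_stack, save_history_csv, train
from .phantom import DIFFICULTIES, render_scan_triple, sample_spec
from .preprocess import filter_blank_frames, make_slab, standardize_stack
from .types import KidneyVolumeRecord, SegmentationMask, UltrasoundStack
from .volumetry import (interscan_variability, mask_volume, records_to_frame,
                        tkv_table)

log = logging.getLogger(__name__)


def simulate_fleet(cfg: ExperimentConfig):
    """Render the phantom cohort.

    Returns ``(scans, demographics)`` where ``scans`` maps
    (patient_id, side) -> list of 3 (stack, mask) sweeps, and demographics is
    a table of synthetic age/height per phantom patient.
    """
    scans: Dict[Tuple[str, str], List] = {}
    demo_rows = []
    k = 0
    for p in range(cfg.n_patients):
        pid = f"PH{p:03d}"
        prng = np.random.default_rng([cfg.seed, 77, p])
        demo_rows.append({"study_id": pid,
                          "sex": "F" if prng.random() < 0.5 else "M",
                          "age": int(prng.integers(25, 71)),
                          "height_m": float(np.round(prng.uniform(1.50, 1.95), 2)),
                          "bmi": float(np.round(prng.uniform(19, 34), 1))})
        for s, side in enumerate(("left", "right")):
            difficulty = cfg.difficulty_mix[k % len(cfg.difficulty_mix)]
            k += 1
            spec = sample_spec(seed=cfg.seed * 4096 + p * 16 + s,
                               difficulty=difficulty, scale=cfg.scale)
            triple = render_scan_triple(spec, jitter_seed=cfg.seed * 131 + k,
                                        patient_id=pid, side=side)
            scans[(pid, side)] = triple
    return scans, pd.DataFrame(demo_rows)


def _build_slab_dataset(scans, patient_ids: List[str],
                        cfg: ExperimentConfig,
                        max_slabs: Optional[int]) -> SlabDataset:
    images, masks, pids = [], [], []
    for (pid, side), triple in sorted(scans.items()):
        if pid not in patient_ids:
            continue
        for stack, mask in triple:
            st, mk = standardize_stack(stack, cfg.preprocess, mask)
            for z in filter_blank_frames(st, cfg.preprocess):
                slab, mslab = make_slab(st, z, cfg.preprocess, mk)
                if cfg.augment.multiplier > 1:
                    for img_a, msk_a in augment_pair(slab, mslab, cfg.augment):
                        images.append(np.asarray(img_a, dtype=np.float32))
                        masks.append(msk_a)
                        pids.append(pid)
                else:
                    images.append(slab)
                    masks.append(mslab)
                    pids.append(pid)
    if max_slabs is not None and len(images) > max_slabs:
        sel = np.linspace(0, len(images) - 1, max_slabs).round().astype(int)
        images = [images[i] for i in sel]
        masks = [masks[i] for i in sel]
        pids = [pids[i] for i in sel]
    return SlabDataset(images=np.stack(images), masks=np.stack(masks),
                       patient_ids=pids)


def run_phantom_experiment(cfg: ExperimentConfig, verbose: bool = False) -> Dict:
    """Run the full pipeline and return the experiment report.

    Any stage failure propagates with a stage-tagged message so a broken run
    is attributable.  All randomness derives from ``cfg.seed``.
    """
    report: Dict = {}
    stage = "config"
    try:
        report["config"] = cfg.as_dict()
        report["config_hash"] = cfg.config_hash()

        stage = "simulate"
        scans, demographics = simulate_fleet(cfg)
        report["n_scans"] = sum(len(t) for t in scans.values())

        stage = "split"
        pids = sorted({pid for pid, _ in scans})
        train_ids, val_ids, test_ids = split_cohort(pids, cfg.ratio(), cfg.seed)
        report["split"] = {"train": train_ids, "val": val_ids, "test": test_ids}

        stage = "preprocess"
        train_ds = _build_slab_dataset(scans, train_ids, cfg, cfg.max_train_slabs)
        val_ds = _build_slab_dataset(scans, val_ids, cfg,
                                     max(cfg.max_train_slabs // 4, 40))

        stage = "train"
        model, _summary = build_unet(cfg.model)
        model, history = train(model, train_ds, val_ds, cfg.model, verbose=verbose)
        report["training"] = {
            "history": history,
            "architecture": model.summary(),
            "best_val_dice": float(np.nanmax([h["val_dice"] for h in history]))
            if history else float("nan"),
        }

        stage = "predict"
        records: List[KidneyVolumeRecord] = []
        reports, deciles = [], []
        paired_ai, paired_gt = [], []
        for (pid, side), triple in sorted(scans.items()):
            in_test = pid in test_ids
            for stack, gt in triple:
                st, mk = standardize_stack(stack, cfg.preprocess, gt)
                records.append(KidneyVolumeRecord(
                    patient_id=pid, side=side, scan_index=stack.scan_index,
                    volume_mL=mask_volume(mk), source="ground_truth"))
                if not in_test:
                    continue
                prob, pred = predict_stack(model, st, cfg.preprocess)
                vol_ai = mask_volume(pred)
                records.append(KidneyVolumeRecord(
                    patient_id=pid, side=side, scan_index=stack.scan_index,
                    volume_mL=vol_ai, source="ai"))
                kept = filter_blank_frames(st, cfg.preprocess)
                reports.append(evaluate_pair(pred, mk, prob=prob, frames=kept))
                if mk.voxels.any():
                    deciles.append(slice_decile_dsc(pred, mk))
                paired_ai.append(vol_ai)
                paired_gt.append(mask_volume(mk))

        stage = "metrics"
        report["metrics"] = {
            "per_scan": [r.as_dict() for r in reports],
            "summary": summarize_reports(reports),
        }
        report["deciles"] = [d.as_row() for d in deciles]

        stage = "volumetry"
        vol_df = records_to_frame(records)
        gt_records = [r for r in records if r.source == "ground_truth"]
        ai_records = [r for r in records if r.source == "ai"]
        report["interscan_mL"] = {"ground_truth": interscan_variability(gt_records)}
        if ai_records:
            report["interscan_mL"]["ai"] = interscan_variability(ai_records)
        tkv_gt = tkv_table(records, "ground_truth")
        report["tkv"] = {"ground_truth": tkv_gt.to_dict("records")}
        tkv_ai = tkv_table(records, "ai") if ai_records else None
        if tkv_ai is not None and len(tkv_ai):
            report["tkv"]["ai"] = tkv_ai.to_dict("records")

        stage = "agreement"
        if len(paired_ai) >= 3:
            report["agreement_ai_vs_truth"] = compare_methods(
                paired_ai, paired_gt).as_dict()

        stage = "classify"
        tables = {"ground_truth": tkv_gt}
        if tkv_ai is not None and len(tkv_ai):
            # classification compares sources on the same (test) patients
            tables["ground_truth"] = tkv_gt[tkv_gt.patient_id.isin(
                tkv_ai.patient_id)].reset_index(drop=True)
            tables["ai"] = tkv_ai
        cls = classify_cohort(tables, demographics)
        report["classification"] = {
            "counts": cls["counts"],
            "labels": cls["labels"],
            "agreement": {
                k: {"cross_tab": v["cross_tab"].to_dict(),
                    "n_agree": v["n_agree"], "n": v["n"],
                    "discordant": v["discordant"]}
                for k, v in cls["agreement"].items()},
        }

        if cfg.out_dir:
            stage = "serialize"
            _serialize(report, vol_df, history, cfg)
    except Exception as exc:
        raise RuntimeError(f"phantom experiment failed at stage {stage!r}: {exc}") from exc
    return report


def _serialize(report: Dict, vol_df: pd.DataFrame, history, cfg: ExperimentConfig) -> None:
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    vol_df.to_csv(os.path.join(out, "volumes.csv"), index=False)
    save_history_csv(history, os.path.join(out, "training_curves.csv"))
    if report.get("metrics", {}).get("per_scan"):
        pd.DataFrame(report["metrics"]["per_scan"]).to_csv(
            os.path.join(out, "metrics_per_scan.csv"), index=False)
    if report.get("deciles"):
        pd.DataFrame(report["deciles"]).to_csv(
            os.path.join(out, "decile_profiles.csv"), index=False)
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    log.info("experiment artifacts written to %s (config %s)",
             out, report["config_hash"])
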