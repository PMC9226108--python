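"""Mask volumetry, patient-level TKV aggregation, and interscan variability.

Total kidney volume per patient follows the clinical rule: left and right
kidney volumes are summed within each scan repetition, then averaged over the
repetitions.  Interscan variability is the cohort-wide mean absolute deviation
of a kidney's three repeated volume measurements from their mean.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import KidneyVolumeRecord, PatientTKV, SegmentationMask

log = logging.getLogger(__name__)


def mask_volume(mask: SegmentationMask) -> float:
    """Volume in mL: foreground voxels x voxel volume (mm^3) / 1000."""
    vox = mask.voxels
    uniq = np.unique(vox)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"mask is not binary: values {uniq[:10]}")
    dx, dy, dz = mask.spacing
    return float(vox.sum()) * dx * dy * dz / 1000.0


def patient_tkv(records: Sequence[KidneyVolumeRecord]) -> PatientTKV:
    """Aggregate one patient+source record set into a total kidney volume.

    For each scan repetition present, both sides must be present; TKV per
    repetition is left + right, and the patient value is the mean over
    repetitions.
    """
    if not records:
        raise ValueError("no records supplied")
    patients = {r.patient_id for r in records}
    sources = {r.source for r in records}
    if len(patients) != 1 or len(sources) != 1:
        raise ValueError(
            f"records must belong to one patient and one source, got "
            f"patients={sorted(patients)} sources={sorted(sources)}")
    by_scan: Dict[int, Dict[str, float]] = defaultdict(dict)
    for r in records:
        if r.side in by_scan[r.scan_index]:
            raise ValueError(
                f"duplicate record for scan {r.scan_index} side {r.side}")
        by_scan[r.scan_index][r.side] = r.volume_mL
    per_scan: List[float] = []
    for scan_index in sorted(by_scan):
        sides = by_scan[scan_index]
        missing = {"left", "right"} - set(sides)
        if missing:
            raise ValueError(
                f"patient {records[0].patient_id}, scan {scan_index}: missing "
                f"{sorted(missing)} kidney volume")
        per_scan.append(sides["left"] + sides["right"])
    return PatientTKV(patient_id=records[0].patient_id,
                      tkv_mL=float(np.mean(per_scan)),
                      n_observations=len(per_scan),
                      source=records[0].source)


def interscan_variability(records: Iterable[KidneyVolumeRecord]) -> float:
    """Mean absolute deviation (mL) of repeated scans from their kidney mean.

    Each kidney contributes its three |v_i - mean(v_1..3)| deviations; the
    statistic is the average of all deviations across kidneys.  Kidneys
    without exactly three scans are excluded with a logged warning.
    """
    by_kidney: Dict[Tuple[str, str, str], List[float]] = defaultdict(list)
    for r in records:
        by_kidney[(r.patient_id, r.side, r.source)].append(r.volume_mL)
    deviations: List[float] = []
    excluded = 0
    for key, vols in sorted(by_kidney.items()):
        if len(vols) != 3:
            excluded += 1
            continue
        m = float(np.mean(vols))
        deviations.extend(abs(v - m) for v in vols)
    if excluded:
        log.warning("interscan_variability: excluded %d kidneys without "
                    "exactly 3 scans", excluded)
    if not deviations:
        raise ValueError("no kidney has exactly 3 scans; nothing to average")
    return float(np.mean(deviations))


# ---------------------------------------------------------------------------
# CSV interchange

_REC_COLS = ["patient_id", "side", "scan_index", "source", "volume_mL"]


def records_to_frame(records: Iterable[KidneyVolumeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.patient_id, r.side, r.scan_index, r.source, r.volume_mL)
         for r in records], columns=_REC_COLS)


def frame_to_records(df: pd.DataFrame) -> List[KidneyVolumeRecord]:
    recs = [KidneyVolumeRecord(patient_id=str(row.patient_id), side=str(row.side),
                               scan_index=int(row.scan_index), source=str(row.source),
                               volume_mL=float(row.volume_mL))
            for row in df.itertuples(index=False)]
    if len({(r.patient_id, r.side, r.scan_index, r.source) for r in recs}) != len(recs):
        raise ValueError("duplicate (patient, side, scan_index, source) rows")
    return recs


def tkv_table(records: Iterable[KidneyVolumeRecord], source: str) -> pd.DataFrame:
    """Patient-level TKV table for one measurement source."""
    by_patient: Dict[str, List[KidneyVolumeRecord]] = defaultdict(list)
    for r in records:
        if r.source == source:
            by_patient[r.patient_id].append(r)
    rows = [patient_tkv(v) for _, v in sorted(by_patient.items())]
    return pd.DataFrame(
        [(t.patient_id, t.tkv_mL, t.n_observations, t.source) for t in rows],
        columns=["patient_id", "tkv_mL", "n_observations", "source"])
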