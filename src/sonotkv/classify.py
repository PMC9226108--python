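"""ADPKD severity classification (Mayo imaging classes 1A-1E) and cohort tables.

The classifier assigns a patient to one of five prognostic groups from
height-adjusted total kidney volume (htTKV = TKV / height, mL/m) and age.
The class boundaries model typical bilateral disease growing from a common
150 mL/m baseline at theoretical age zero with compound annual growth rates
of 1.5, 3, 4.5 and 6 %/yr: the boundary between adjacent classes at age A is
``150 * (1 + r)^A``.  Severity increases 1A -> 1E.  Only typical (Class 1)
bilateral morphology is modelled.

The boundary formula is isolated in :func:`class_thresholds` so an
alternative parameterization can be swapped in without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

LABELS = ("1A", "1B", "1C", "1D", "1E")
GROWTH_RATES = (0.015, 0.03, 0.045, 0.06)  # annual, between adjacent classes
BASELINE_HTTKV = 150.0                      # mL/m at age 0
MIN_AGE = 15.0                              # model domain lower bound, years


@dataclass(frozen=True)
class MayoInput:
    age: float       # years
    height: float    # metres
    tkv_mL: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.height <= 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if self.tkv_mL < 0:
            raise ValueError(f"tkv_mL must be non-negative, got {self.tkv_mL}")


@dataclass(frozen=True)
class MayoClass:
    label: str
    httkv_mL_per_m: float
    boundary_values: Tuple[float, float, float, float]
    out_of_domain: bool = False


def class_thresholds(age: float) -> Tuple[float, float, float, float]:
    """The four htTKV boundaries (mL/m) separating 1A|1B|1C|1D|1E at ``age``."""
    return tuple(BASELINE_HTTKV * (1.0 + r) ** age for r in GROWTH_RATES)


def mayo_classify(inp: MayoInput) -> MayoClass:
    """Assign a severity class from age, height and TKV.

    Bands are half-open [lower, upper): a value exactly on a boundary goes to
    the higher (more severe) class — conservative toward risk, and patients
    do land on boundaries once interscan variability is considered.
    Ages at or below the model's domain bound (15 y) are classified anyway
    but flagged out-of-domain.
    """
    httkv = inp.tkv_mL / inp.height
    bounds = class_thresholds(inp.age)
    label = LABELS[int(np.searchsorted(bounds, httkv, side="right"))]
    return MayoClass(label=label, httkv_mL_per_m=float(httkv),
                     boundary_values=bounds,
                     out_of_domain=bool(inp.age <= MIN_AGE))


def classify_cohort(tkv_tables: Dict[str, pd.DataFrame],
                    demographics: pd.DataFrame) -> Dict:
    """Class counts per measurement source plus pairwise agreement tables.

    ``tkv_tables`` maps a source name to a table with columns
    ``patient_id, tkv_mL``; ``demographics`` has ``study_id, age, height_m``.
    Every patient in a TKV table must appear in the demographics.
    """
    demo = demographics.set_index("study_id")
    per_patient: Dict[str, Dict[str, str]] = {}
    counts: Dict[str, Dict[str, int]] = {}
    for source, table in tkv_tables.items():
        labels: Dict[str, str] = {}
        for row in table.itertuples(index=False):
            pid = str(row.patient_id)
            if pid not in demo.index:
                raise ValueError(
                    f"patient {pid!r} (source {source!r}) missing from demographics")
            d = demo.loc[pid]
            cls = mayo_classify(MayoInput(age=float(d["age"]),
                                          height=float(d["height_m"]),
                                          tkv_mL=float(row.tkv_mL)))
            labels[pid] = cls.label
        per_patient[source] = labels
        counts[source] = {lab: sum(1 for v in labels.values() if v == lab)
                          for lab in LABELS}

    agreement: Dict[str, Dict] = {}
    sources = sorted(tkv_tables)
    for i, s1 in enumerate(sources):
        for s2 in sources[i + 1:]:
            common = sorted(set(per_patient[s1]) & set(per_patient[s2]))
            tab = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS))
            discordant: List[Dict] = []
            for pid in common:
                a, b = per_patient[s1][pid], per_patient[s2][pid]
                tab.loc[a, b] += 1
                if a != b:
                    discordant.append({"patient_id": pid, s1: a, s2: b})
            agreement[f"{s1}_vs_{s2}"] = {
                "cross_tab": tab,
                "n_agree": int(np.trace(tab.values)),
                "n": len(common),
                "discordant": discordant,
            }
    return {"counts": counts, "labels": per_patient, "agreement": agreement}
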