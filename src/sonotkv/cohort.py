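"""Cohort-table ingestion and demographic summaries.

Ships a packaged 22-patient ADPKD reference cohort (sex, age, height, BMI) so
demographic summaries and classification demos run fully offline.  BMI bands
follow the clinical convention with contiguous half-open intervals: normal
[18.5, 25), overweight [25, 30), obese >= 30; underweight (< 18.5) is counted
separately when present.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, asdict
from typing import Dict, List

import numpy as np
import pandas as pd

REQUIRED_COLS = ["study_id", "sex", "age", "height_m", "bmi"]


def _round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding of a float's shortest repr (1.675 -> 1.68)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    # pre-round well past the display precision so 1.6749999999999998,
    # the float for the exact data median 1.675, rounds as 1.675 does
    return float(Decimal(repr(round(float(x), ndigits + 6))).quantize(
        q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n: int
    n_female: int
    n_male: int
    pct_female: float
    mean_age: float
    median_age: float
    min_age: float
    max_age: float
    mean_height: float
    median_height: float
    bmi_underweight: int
    bmi_normal: int
    bmi_overweight: int
    bmi_obese: int

    def as_dict(self) -> Dict:
        return asdict(self)

    def display(self) -> Dict:
        """Rounded for presentation: ages to integers, heights to 2 dp.

        Half-up decimal rounding, so a median height of 1.675 m reads 1.68.
        """
        d = self.as_dict()
        for k in ("mean_age", "median_age", "min_age", "max_age", "pct_female"):
            d[k] = int(_round_half_up(d[k], 0))
        for k in ("mean_height", "median_height"):
            d[k] = _round_half_up(d[k], 2)
        return d


def reference_cohort() -> pd.DataFrame:
    """The packaged 22-patient ADPKD demographics table."""
    with importlib.resources.files("sonotkv.data").joinpath(
            "adpkd_cohort_demographics.csv").open() as fh:
        return pd.read_csv(fh)


def load_cohort(path: str) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    bad: List[str] = []
    if table["study_id"].duplicated().any():
        dup = table.loc[table["study_id"].duplicated(), "study_id"].tolist()
        bad.append(f"duplicate study_id rows: {dup}")
    for idx, row in table.iterrows():
        if row["sex"] not in ("M", "F"):
            bad.append(f"row {idx} ({row['study_id']}): sex {row['sex']!r}")
        if not 0 < row["age"] < 120:
            bad.append(f"row {idx} ({row['study_id']}): age {row['age']}")
        if not 0.5 < row["height_m"] < 2.5:
            bad.append(f"row {idx} ({row['study_id']}): height {row['height_m']}")
        if not row["bmi"] > 0:
            bad.append(f"row {idx} ({row['study_id']}): bmi {row['bmi']}")
    if bad:
        raise ValueError("cohort table invalid: " + "; ".join(bad))
    return table


def summarize_cohort(table: pd.DataFrame) -> CohortSummary:
    table = validate_cohort(table)
    if len(table) == 0:
        raise ValueError("cohort table is empty")
    ages = table["age"].to_numpy(dtype=float)
    heights = table["height_m"].to_numpy(dtype=float)
    bmi = table["bmi"].to_numpy(dtype=float)
    n = len(table)
    nf = int((table["sex"] == "F").sum())
    return CohortSummary(
        n=n,
        n_female=nf,
        n_male=n - nf,
        pct_female=100.0 * nf / n,
        mean_age=float(ages.mean()),
        median_age=float(np.median(ages)),
        min_age=float(ages.min()),
        max_age=float(ages.max()),
        mean_height=float(heights.mean()),
        median_height=float(np.median(heights)),
        bmi_underweight=int((bmi < 18.5).sum()),
        bmi_normal=int(((bmi >= 18.5) & (bmi < 25)).sum()),
        bmi_overweight=int(((bmi >= 25) & (bmi < 30)).sum()),
        bmi_obese=int((bmi >= 30).sum()),
    )
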