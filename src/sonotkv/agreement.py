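"""Method-comparison statistics: OLS R-squared and percent Bland-Altman.

Kidney volumes span an order of magnitude across a cohort, so differences are
expressed on the percent scale: d_i = 100 * (m1_i - m2_i) / mean(m1_i, m2_i).
Bias is the mean difference, limits of agreement are bias +/- 1.96 SD, and
bias significance is judged by whether zero lies outside the t-based 95%
confidence interval of the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import stats


@dataclass
class AgreementResult:
    r2: float
    bias_pct: float
    loa_low_pct: float
    loa_high_pct: float
    bias_ci_low_pct: float
    bias_ci_high_pct: float
    bias_significant: bool
    n: int

    def as_dict(self) -> Dict:
        return {k: getattr(self, k) for k in (
            "r2", "bias_pct", "loa_low_pct", "loa_high_pct",
            "bias_ci_low_pct", "bias_ci_high_pct", "bias_significant", "n")}


def linear_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination of ordinary least squares y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; R^2 undefined")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)


def bland_altman_percent(m1: Sequence[float], m2: Sequence[float],
                         loa_multiplier: float = 1.96,
                         ci_level: float = 0.95) -> AgreementResult:
    """Percent-scale Bland-Altman comparison of two paired volume series."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError(f"length mismatch: {m1.shape} vs {m2.shape}")
    n = m1.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    means = (m1 + m2) / 2.0
    if (means <= 0).any():
        bad = int(np.argmax(means <= 0))
        raise ValueError(
            f"pair {bad} has non-positive mean ({means[bad]:.3f}); percent "
            f"differences are undefined")
    d = 100.0 * (m1 - m2) / means
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - loa_multiplier * sd, bias + loa_multiplier * sd
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1))
    half = tcrit * sd / np.sqrt(n)
    ci_low, ci_high = bias - half, bias + half
    significant = not (ci_low <= 0.0 <= ci_high)
    return AgreementResult(
        r2=float("nan"), bias_pct=bias, loa_low_pct=float(loa_low),
        loa_high_pct=float(loa_high), bias_ci_low_pct=float(ci_low),
        bias_ci_high_pct=float(ci_high), bias_significant=significant, n=int(n))


def compare_methods(m1: Sequence[float], m2: Sequence[float]) -> AgreementResult:
    """R-squared plus percent Bland-Altman for one method pair."""
    res = bland_altman_percent(m1, m2)
    res.r2 = linear_r2(m1, m2)
    return res
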