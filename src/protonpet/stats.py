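"""Group summaries and the independent-samples t-test.

The clip analysis compares mean dR50 between groups (clip vs control
ROI, shallow vs deep clips) with an independent two-sample t-test.
Pooled-variance Student's t is the default, matching the usual clinical
"Independent Samples T-Test"; Welch's unequal-variance variant is
available by flag. The 0.05 significance threshold is reported alongside
p values but never gates any computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupStats:
    n: int
    mean_mm: float
    sd_mm: float  # n-1 sample SD; NaN when n < 2


@dataclass
class TTestResult:
    t_stat: float
    df: float
    p_two_sided: float
    variant: str  # "pooled" | "welch"


def group_summary(values) -> GroupStats:
    """Mean and n-1 sample SD of a group of dR50 values."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("group is empty")
    if not np.all(np.isfinite(v)):
        raise ValueError("group contains non-finite values")
    sd = float(v.std(ddof=1)) if v.size >= 2 else float("nan")
    return GroupStats(n=int(v.size), mean_mm=float(v.mean()), sd_mm=sd)


def independent_t_test(a, b, variant: str = "pooled") -> TTestResult:
    """Two-sided independent-samples t-test between groups a and b.

    ``pooled`` uses the classical pooled-variance Student's t with
    df = n_a + n_b - 2; ``welch`` uses unequal variances with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = float(a.size + b.size - 2) if variant == "pooled" else float(res.df)
    return TTestResult(t_stat=float(res.statistic), df=df,
                       p_two_sided=float(res.pvalue), variant=variant)
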