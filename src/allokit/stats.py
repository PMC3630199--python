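"""Distribution statistics for ensemble comparison.

Normality of per-frame metric distributions is assessed with the
Shapiro-Wilk test; differences between the two ensembles' metric means
with a two-sample Student's t test (Welch by default).  p-values below
2.2e-16 are reported as "< 2.2e-16", the conventional double-precision
floor.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

__all__ = ["shapiro_wilk", "students_t", "format_p", "P_FLOOR"]

P_FLOOR = 2.2e-16
SHAPIRO_MAX_N = 5000


def shapiro_wilk(
    values, max_n: int = SHAPIRO_MAX_N, seed: int = 0
) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value.

    Series longer than ``max_n`` are subsampled without replacement with a
    fixed seed (the test's calibration range ends at n = 5000).  Constant
    series are rejected, as W is undefined for them.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("shapiro_wilk needs a 1-D series with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("shapiro_wilk is undefined for a constant series")
    if x.size > max_n:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_n, replace=False)
    w, p = _stats.shapiro(x)
    return float(w), float(p)


def students_t(
    group_a, group_b, variant: str = "welch"
) -> tuple[float, float, float]:
    """Two-sample two-sided t test: returns (t, degrees of freedom, p).

    ``variant`` is ``"welch"`` (unequal variances, default) or
    ``"pooled"`` (classic equal-variance Student's test).  Two groups with
    zero variance and equal means return t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        df = float(a.size + b.size - 2)
        if a[0] == b[0]:
            return 0.0, df, 1.0
        return float("inf") * np.sign(a[0] - b[0]), df, 0.0
    res = _stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def format_p(p: float) -> str:
    """Render a p-value, flooring at the double-precision convention."""
    if p < P_FLOOR:
        return "< 2.2e-16"
    return f"{p:.3g}"
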