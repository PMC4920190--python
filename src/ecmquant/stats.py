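"""Group summaries and the unpaired t-tests used to compare conditions.

Readouts (contraction %, alignment score, thickness, modulus) are compared
between conditions as mean +- s.e.m. with two-sided unpaired t-tests.  The
default is the pooled-variance Student's test; Welch's correction is
behind a flag.  No multiple-testing correction is applied — a caveat when
many condition pairs are screened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    """Mean +- s.e.m. of one condition group (sd with n-1 denominator)."""

    label: str
    n: int
    mean: float
    sem: float
    values: np.ndarray = field(repr=False)


def summarize(values, label: str = "") -> GroupSummary:
    """Mean, s.e.m. (sd/sqrt(n), ddof=1) and n of a group of measurements.

    A single observation has undefined s.e.m.; it is reported as 0 with a
    warning so degenerate groups still tabulate.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty group")
    if arr.size == 1:
        warnings.warn(f"group {label!r} has n=1; s.e.m. undefined, reporting 0",
                      stacklevel=2)
        sem = 0.0
    else:
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return GroupSummary(label=label, n=int(arr.size), mean=float(arr.mean()),
                        sem=sem, values=arr)


def unpaired_t_test(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; returns ``(t, df, p)``.

    Pooled-variance Student's test by default; ``welch=True`` applies the
    Welch-Satterthwaite correction for unequal variances.
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)
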