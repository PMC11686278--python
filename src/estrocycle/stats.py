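"""Group-comparison statistics: t-tests, Pearson correlation, and the
Holm-Sidak step-down multiple-comparison adjustment.

Unpaired comparisons default to Welch's unequal-variance t-test; adjusted
p-values use the step-down Sidak bound 1 - (1 - p_(i))^(m - i + 1) with
monotone enforcement, reported in the input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError, DegenerateDataError


@dataclass
class ComparisonResult:
    test: str                 # paired_t | unpaired_t | pearson
    statistic: float
    df: float
    p_raw: float
    degenerate: bool = False  # e.g. zero-variance paired differences


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sort ascending; the i-th smallest of m raw p-values is adjusted to
    1 - (1 - p)^(m - i), i = 0..m-1, then a running maximum enforces
    monotonicity before restoring the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise DataError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def t_test(x, y, paired: bool = False) -> ComparisonResult:
    """Two-tailed t-test; Welch's form for unpaired comparisons.

    Paired comparisons with zero-variance differences are flagged
    degenerate (the statistic is unbounded); identical paired inputs give
    statistic 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("need n >= 2 per group")
    if paired:
        if len(x) != len(y):
            raise DataError("paired test requires equal lengths")
        diffs = x - y
        if np.all(diffs == diffs[0]):
            if diffs[0] == 0:
                return ComparisonResult("paired_t", 0.0, len(x) - 1, 1.0)
            return ComparisonResult("paired_t", float("inf"), len(x) - 1,
                                    0.0, degenerate=True)
        res = sps.ttest_rel(x, y)
        return ComparisonResult("paired_t", float(res.statistic),
                                float(res.df), float(res.pvalue))
    res = sps.ttest_ind(x, y, equal_var=False)
    return ComparisonResult("unpaired_t", float(res.statistic),
                            float(res.df), float(res.pvalue))


def pearson(x, y) -> ComparisonResult:
    """Pearson correlation with a two-tailed p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in one of the inputs")
    res = sps.pearsonr(x, y)
    return ComparisonResult("pearson", float(res.statistic),
                            float(len(x) - 2), float(res.pvalue))
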