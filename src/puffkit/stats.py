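"""Expression normalization and the small statistical toolkit.

Raw fluorescence intensities are not comparable across imaging sessions, so
expression is reported as 10,000 x F_sample / F_beads, where F_beads is the
fluorescence of reference beads imaged under the same settings.  Group
comparisons use the classical equal-variance Student's t test (Welch by
flag), correlations the Pearson coefficient, and ordered frequency
distributions the Cochran-Armitage chi-square test for trend.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
from scipy import stats as sps

__all__ = ["normalize_expression", "compare_groups", "pearson_points", "chi2_trend"]

TtestResult = namedtuple("TtestResult", ["t", "df", "p"])
PearsonResult = namedtuple("PearsonResult", ["r", "p"])
TrendResult = namedtuple("TrendResult", ["chi2", "p"])


def normalize_expression(f_sample: float, f_beads: float) -> float:
    """Bead-normalized fluorescence: 10,000 x f_sample / f_beads."""
    if f_beads <= 0:
        raise ValueError("reference bead fluorescence must be > 0")
    return 10_000.0 * np.asarray(f_sample, float) / f_beads


def compare_groups(values_a, values_b, equal_var: bool = True) -> TtestResult:
    """Unpaired two-sided t test between two groups.

    Classical equal-variance (Student's) by default; set ``equal_var=False``
    for Welch.  Returns the t statistic, degrees of freedom and two-sided p.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
        if sp2 == 0:
            raise ValueError("zero pooled variance; t undefined")
    else:
        df = res.df
    return TtestResult(float(res.statistic), float(df), float(res.pvalue))


def pearson_points(x, y) -> PearsonResult:
    """Pearson correlation of paired points, p from the t transform of r."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        return PearsonResult(float("nan"), float("nan"))
    r, p = sps.pearsonr(x, y)
    return PearsonResult(float(r), float(p))


def chi2_trend(counts_table, scores=None) -> TrendResult:
    """Cochran-Armitage chi-square test for trend on a 2 x k table.

    Rows are the binary outcome, columns the ordered categories.  With
    equally spaced ``scores`` (default 0..k-1) the statistic is

        chi2 = U^2 / Var(U),  U = sum_j s_j n_1j - R1 sum_j s_j c_j / N,
        Var(U) = R1 R2 (N sum_j s_j^2 c_j - (sum_j s_j c_j)^2) / (N^2 (N-1)),

    with 1 degree of freedom.  Symmetric in the two rows.
    """
    tab = np.asarray(counts_table, float)
    if tab.ndim != 2 or tab.shape[0] != 2 or tab.shape[1] < 2:
        raise ValueError("counts_table must be 2 x k with k >= 2")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    col = tab.sum(axis=0)
    row = tab.sum(axis=1)
    if (col == 0).any() or (row == 0).any():
        raise ValueError("zero margin in the table; trend undefined")
    k = tab.shape[1]
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, float)
    if len(s) != k:
        raise ValueError("scores must match the number of columns")
    n = tab.sum()
    u = (s * tab[0]).sum() - row[0] * (s * col).sum() / n
    var = row[0] * row[1] * (n * (s ** 2 * col).sum() - ((s * col).sum()) ** 2) / (n ** 2 * (n - 1))
    if var <= 0:
        raise ValueError("degenerate table; trend variance is zero")
    chi2 = u * u / var
    return TrendResult(float(chi2), float(sps.chi2.sf(chi2, df=1)))
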