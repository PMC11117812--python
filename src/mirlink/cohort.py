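"""Cohort statistics: robust outlier detection, normality-gated two-group
tests, 2x2 chi-square, and baseline-table assembly.

Continuous variables can be compared either from raw samples (Shapiro-Wilk
gate choosing Student t or Mann-Whitney) or from printed (mean, SD, n)
summaries (pooled-variance Student t only - the only test computable from
summaries). Categorical variables use the uncorrected Pearson chi-square
on counts reconstructed from printed percentages, which is the convention
that reproduces published 2x2 p-values computed without continuity
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatTestResult",
    "rout_outliers",
    "compare_continuous",
    "compare_categorical",
    "baseline_table",
]


@dataclass
class StatTestResult:
    test_name: str  # student_t | mann_whitney | chi_square
    statistic: float
    pvalue: float
    df: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of range: {self.pvalue}")


def rout_outliers(values, q: float = 0.01) -> frozenset[int]:
    """ROUT-style robust outlier detection for a single sample.

    Specialization of robust-regression-and-outlier-removal to the constant
    model: residuals from the median, a robust SD (RSDR) from the 68.27th
    percentile of absolute residuals with the n/(n-1) small-sample
    correction, two-tailed t tail probabilities of residual/RSDR, and a
    false-discovery step-up at rate ``q`` flagging the most extreme points.

    Returns the set of flagged indices. With n < 3, or a zero RSDR (all
    values identical), no detection is performed.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        warnings.warn("ROUT needs n >= 3; no outlier detection performed", stacklevel=2)
        return frozenset()
    if not (0 < q < 1):
        raise ValueError("Q must lie in (0, 1)")
    resid = values - np.median(values)
    abs_resid = np.abs(resid)
    rsdr = np.percentile(abs_resid, 68.27) * n / (n - 1)
    if rsdr == 0:
        return frozenset()
    t = abs_resid / rsdr
    pvals = 2.0 * stats.t.sf(t, df=n - 1)
    order = np.argsort(pvals, kind="mergesort")
    flagged: frozenset[int] = frozenset()
    # step-up: largest i with p_(i) <= Q * i / n flags the i most extreme points
    for i in range(n, 0, -1):
        if pvals[order[i - 1]] <= q * i / n:
            flagged = frozenset(int(j) for j in order[:i])
            break
    return flagged


def _pooled_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> StatTestResult:
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return StatTestResult("student_t", 0.0, 1.0, df=n1 + n2 - 2,
                                  note="degenerate: zero variance, equal means")
        return StatTestResult("student_t", np.inf, 0.0, df=n1 + n2 - 2,
                              note="degenerate: zero variance, unequal means")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return StatTestResult("student_t", float(t), float(p), df=n1 + n2 - 2)


def compare_continuous(
    a=None,
    b=None,
    summary_a: tuple[float, float, int] | None = None,
    summary_b: tuple[float, float, int] | None = None,
    force_test: str = "auto",
    shapiro_alpha: float = 0.05,
) -> StatTestResult:
    """Two-sided two-group comparison of a continuous variable.

    With raw samples and ``force_test='auto'``: Shapiro-Wilk on each group;
    pooled-variance Student t if both pass at ``shapiro_alpha``, otherwise
    Mann-Whitney (exact when both groups have n <= 8 and no ties).
    With (mean, sd, n) summaries: pooled-variance Student t only.
    """
    if summary_a is not None or summary_b is not None:
        if summary_a is None or summary_b is None:
            raise ValueError("both group summaries are required")
        if force_test == "mann_whitney":
            raise ValueError("Mann-Whitney cannot be computed from summaries")
        m1, s1, n1 = summary_a
        m2, s2, n2 = summary_b
        if n1 < 2 or n2 < 2:
            raise ValueError("each group needs n >= 2")
        if s1 < 0 or s2 < 0:
            raise ValueError("sd must be >= 0")
        result = _pooled_t_from_stats(m1, s1, n1, m2, s2, n2)
        result.note = (result.note + "; " if result.note else "") + "computed-from-summaries"
        return result

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    test = force_test
    if test == "auto":
        gaussian = all(
            np.ptp(g) > 0 and stats.shapiro(g).pvalue > shapiro_alpha for g in (a, b)
        ) or (np.ptp(a) == 0 and np.ptp(b) == 0)
        test = "student_t" if gaussian else "mann_whitney"
    if test == "student_t":
        if np.ptp(np.concatenate([a, b])) == 0:
            return StatTestResult("student_t", 0.0, 1.0, df=a.size + b.size - 2,
                                  note="degenerate: constant data")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return StatTestResult("student_t", float(t), float(p), df=a.size + b.size - 2)
    if test == "mann_whitney":
        method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return StatTestResult("mann_whitney", float(u), float(p))
    raise ValueError(f"unknown test {force_test!r}")


def compare_categorical(k1: int, n1: int, k2: int, n2: int) -> StatTestResult:
    """Uncorrected Pearson chi-square on the 2x2 table (k, n-k) x 2 groups."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        return StatTestResult("chi_square", 0.0, 1.0, df=1.0,
                              note="degenerate: zero expected cell")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return StatTestResult("chi_square", float(chi2), float(p), df=float(df))


def baseline_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Group-comparison p-values for a baseline-characteristics table.

    ``clinical`` holds one row per variable with columns
    variable, kind ('continuous'/'categorical') and, for two group labels
    X and Y, ``X_mean``/``X_sd``/``X_n`` (continuous) or ``X_percent``/``X_n``
    (categorical). Continuous rows use the pooled-variance Student t from
    the summaries; categorical rows use the uncorrected chi-square on
    counts reconstructed as round(percent / 100 * n). An optional
    ``printed_p`` column is carried through with a ``matches_printed`` flag
    (|computed - printed| <= 1e-3), so rows a published table reports from
    a different procedure are surfaced rather than forced.
    """
    labels = sorted(
        {c.rsplit("_", 1)[0] for c in clinical.columns if c.endswith("_n")}
    )
    if len(labels) != 2:
        raise ValueError(f"expected two group label prefixes, found {labels}")
    g1, g2 = labels
    rows = []
    for rec in clinical.itertuples(index=False):
        rec = rec._asdict()
        kind = rec["kind"]
        if kind == "continuous":
            result = compare_continuous(
                summary_a=(rec[f"{g1}_mean"], rec[f"{g1}_sd"], int(rec[f"{g1}_n"])),
                summary_b=(rec[f"{g2}_mean"], rec[f"{g2}_sd"], int(rec[f"{g2}_n"])),
            )
        elif kind == "categorical":
            counts = []
            for g in (g1, g2):
                pct, n = float(rec[f"{g}_percent"]), int(rec[f"{g}_n"])
                if not (0 <= pct <= 100):
                    raise ValueError(f"{rec['variable']}: percent out of [0, 100]")
                exact = pct / 100.0 * n
                k = int(round(exact))
                if abs(exact - k) > 0.51:
                    warnings.warn(
                        f"{rec['variable']}: percent {pct} with n={n} does not "
                        "round to an integer count", stacklevel=2,
                    )
                counts.extend([k, n])
            result = compare_categorical(*counts)
        else:
            raise ValueError(f"{rec['variable']}: unknown kind {kind!r}")
        row = {
            "variable": rec["variable"],
            "kind": kind,
            "test": result.test_name,
            "statistic": result.statistic,
            "pvalue": result.pvalue,
            "note": result.note,
        }
        if "printed_p" in rec and not pd.isna(rec["printed_p"]):
            printed = str(rec["printed_p"])
            printed_val = 1.0 if printed.startswith(">") else float(printed)
            row["printed_p"] = printed
            row["matches_printed"] = bool(abs(result.pvalue - printed_val) <= 1e-3)
        rows.append(row)
    return pd.DataFrame(rows)
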