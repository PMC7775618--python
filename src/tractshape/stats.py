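"""Reliability and asymmetry statistics for shape descriptors.

Test-retest reliability uses the one-way random-effects, single-measures
intraclass correlation ICC(1,1): with n subjects measured in k = 2
sessions, a one-way ANOVA over subjects gives between-subject and
within-subject mean squares, and

    ICC(1,1) = (MS_between - MS_within) / (MS_between + (k-1) MS_within).

Values at or above 0.75 are categorized as good reliability, values in
[0.5, 0.75) as moderate, and values below 0.5 as poor.  Negative ICCs
are reported as computed rather than floored at zero, since flooring
hides degenerate reliability.

Left-right asymmetry is assessed with two-sided paired t-tests, an
effect size (Cohen's d, paired form mean(diff)/sd(diff) by default), and
a percentage difference 100 x (a - b) / a where a is the side with the
larger mean (the dominant side).  Between-subject variation of a
descriptor is the absolute deviation from the median divided by the
median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AsymmetryResult",
    "icc_1_1",
    "categorize_reliability",
    "reliability_table",
    "significance_stars",
    "asymmetry_test",
    "between_subject_deviation",
    "deviation_summary",
]

GOOD_ICC = 0.75
MODERATE_ICC = 0.5


def icc_1_1(session1, session2) -> float:
    """One-way random, single-measures intraclass correlation.

    Symmetric in session order and invariant under a common affine
    transform of all measurements.  Raises on fewer than 3 subjects or
    zero total variance (ICC undefined).
    """
    x1 = np.asarray(session1, dtype=float)
    x2 = np.asarray(session2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("sessions must be equal-length 1D arrays")
    n = x1.size
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    data = np.column_stack([x1, x2])
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    ss_between = k * np.sum((subj_means - grand) ** 2)
    ss_within = np.sum((data - subj_means[:, None]) ** 2)
    if ss_between + ss_within == 0:
        raise ValueError("ICC is undefined: all measurements are identical (zero variance)")
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    return float((ms_between - ms_within) / (ms_between + (k - 1) * ms_within))


def categorize_reliability(icc: float) -> str:
    """'good' (ICC >= 0.75), 'moderate' (0.5 <= ICC < 0.75), else 'poor'."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc >= GOOD_ICC:
        return "good"
    if icc >= MODERATE_ICC:
        return "moderate"
    return "poor"


def reliability_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Per bundle-descriptor ICC and category from a tidy cohort table.

    ``tidy`` columns: subject, session (two distinct values), bundle,
    descriptor, value.  Returns one row per (bundle, descriptor) with
    columns icc and category, plus the per-descriptor median ICC across
    bundles in an attached ``median_icc`` attribute-style column merge.
    """
    required = {"subject", "session", "bundle", "descriptor", "value"}
    missing = required - set(tidy.columns)
    if missing:
        raise ValueError(f"tidy table is missing columns: {sorted(missing)}")
    sessions = sorted(tidy["session"].unique())
    if len(sessions) != 2:
        raise ValueError(f"expected exactly 2 sessions, found {len(sessions)}")
    rows = []
    for (bundle, desc), grp in tidy.groupby(["bundle", "descriptor"], sort=True):
        wide = grp.pivot_table(index="subject", columns="session", values="value")
        wide = wide.dropna()
        icc = icc_1_1(wide[sessions[0]].values, wide[sessions[1]].values)
        rows.append(
            {
                "bundle": bundle,
                "descriptor": desc,
                "icc": icc,
                "category": categorize_reliability(icc),
            }
        )
    table = pd.DataFrame(rows)
    median = table.groupby("descriptor")["icc"].median().rename("median_icc")
    return table.merge(median, on="descriptor")


def significance_stars(p: float) -> str:
    """'***' for p < 0.001, '**' for p < 0.01, '*' for p < 0.05, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AsymmetryResult:
    """Paired left-right comparison for one bundle-descriptor."""

    p_value: float
    stars: str
    percent_difference: float  # 100 * (a - b) / a, a = dominant side mean
    cohens_d: float
    dominant: str  # "left" | "right"
    degenerate: bool = False  # zero difference variance


def asymmetry_test(left, right, d_form: str = "paired") -> AsymmetryResult:
    """Two-sided paired t-test of left vs right with effect sizes.

    ``d_form='paired'`` (default) uses mean(diff)/sd(diff); ``'pooled'``
    divides the mean difference by the pooled standard deviation of the
    two sides.  Zero difference variance is flagged degenerate (the
    t-test is undefined); the percent difference is still reported.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("left and right must be equal-length 1D arrays")
    if left.size < 3:
        raise ValueError("paired test requires at least 3 subjects")
    diff = left - right
    sd_diff = diff.std(ddof=1)

    a_is_left = left.mean() >= right.mean()
    a, b = (left, right) if a_is_left else (right, left)
    pct = 100.0 * (a.mean() - b.mean()) / a.mean() if a.mean() != 0 else np.nan

    if sd_diff == 0:
        return AsymmetryResult(
            p_value=np.nan,
            stars="",
            percent_difference=float(pct),
            cohens_d=np.nan,
            dominant="left" if a_is_left else "right",
            degenerate=True,
        )

    t_res = sps.ttest_rel(left, right)
    if d_form == "paired":
        d = diff.mean() / sd_diff
    elif d_form == "pooled":
        pooled = np.sqrt((left.var(ddof=1) + right.var(ddof=1)) / 2)
        d = diff.mean() / pooled
    else:
        raise ValueError("d_form must be 'paired' or 'pooled'")
    return AsymmetryResult(
        p_value=float(t_res.pvalue),
        stars=significance_stars(float(t_res.pvalue)),
        percent_difference=float(pct),
        cohens_d=float(d),
        dominant="left" if a_is_left else "right",
    )


def between_subject_deviation(values) -> np.ndarray:
    """Per-subject |x - median| / median (dimensionless)."""
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    if med == 0:
        raise ValueError("between-subject deviation is undefined for zero median")
    return np.abs(x - med) / med


def deviation_summary(deviations) -> dict:
    """Median and quartiles of a collection of deviation values."""
    d = np.asarray(deviations, dtype=float)
    return {
        "median": float(np.median(d)),
        "q1": float(np.percentile(d, 25)),
        "q3": float(np.percentile(d, 75)),
    }
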