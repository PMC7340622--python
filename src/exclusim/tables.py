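"""Baseline-imbalance testing: chi-squared, pooled t, Wilcoxon rank sum.

These are the tests used to compare baseline characteristics between the
low- and high-UE halves of a cohort: Pearson chi-squared (no continuity
correction) for categorical variables, the pooled-variance two-sample t
for approximately symmetric numeric variables, and the Wilcoxon rank-sum
test for skewed ones (age, insulin-30).  ``build_baseline_table`` assembles
the full comparison table with the formatting conventions of a clinical
baseline table (percents to 1 decimal, p-values to 4 decimals).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "chi_squared_test",
    "pooled_t_test",
    "wilcoxon_rank_sum",
    "BaselineComparisonRow",
    "build_baseline_table",
    "render_baseline_table",
]


def chi_squared_test(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction.  Returns (statistic, df, p).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    rows_zero = np.where(t.sum(axis=1) == 0)[0]
    cols_zero = np.where(t.sum(axis=0) == 0)[0]
    if rows_zero.size or cols_zero.size:
        raise ValueError(
            f"zero marginal: rows {rows_zero.tolist()}, columns {cols_zero.tolist()}"
        )
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def pooled_t_test(
    mean1=None, sd1=None, n1=None, mean2=None, sd2=None, n2=None,
    sample1=None, sample2=None,
) -> tuple[float, int, float]:
    """Student pooled-variance two-sample t-test, two-sided.

    Accepts either summary statistics (mean, sd, n per group) or raw
    samples.  Returns (t, df, p).  The degenerate case of zero pooled
    variance with unequal means yields p = 0 (and an infinite t).
    """
    if sample1 is not None or sample2 is not None:
        s1 = np.asarray(sample1, dtype=float)
        s2 = np.asarray(sample2, dtype=float)
        mean1, sd1, n1 = s1.mean(), s1.std(ddof=1), s1.size
        mean2, sd2, n2 = s2.mean(), s2.std(ddof=1), s2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        return float(np.sign(mean1 - mean2) * np.inf), df, 0.0
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def _rank_sum_exact_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p by full enumeration of group-1 rank assignments.

    Works with mid-ranks, so ties are handled by enumerating the observed
    (possibly tied) rank multiset.  Intended for n1 + n2 <= 12.
    """
    sums = np.fromiter(
        (sum(c) for c in combinations(ranks, n1)), dtype=float,
        count=comb(ranks.size, n1),
    )
    mu = ranks.sum() * n1 / ranks.size
    dev = abs(w_obs - mu)
    p = np.mean(np.abs(sums - mu) >= dev - 1e-12)
    return float(min(1.0, p))


def wilcoxon_rank_sum(sample1, sample2, exact_max_n: int = 12) -> tuple[float, float]:
    """Wilcoxon rank-sum test with mid-ranks for ties.

    Exact enumeration of all rank assignments when n1 + n2 <= *exact_max_n*;
    otherwise the normal approximation with tie-corrected variance and a
    0.5 continuity correction.  Returns (rank-sum statistic of sample 1, p).
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([s1, s2])
    if np.all(pooled == pooled[0]):
        n1 = s1.size
        return float(n1 * (pooled.size + 1) / 2.0), 1.0
    ranks = stats.rankdata(pooled)  # mid-ranks
    n1, n = s1.size, pooled.size
    w = float(ranks[:n1].sum())
    if n <= exact_max_n:
        return w, _rank_sum_exact_p(ranks, n1, w)
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return w, float(min(1.0, p))


@dataclass
class BaselineComparisonRow:
    variable: str
    summary_total: str
    summary_low: str
    summary_high: str
    test: str
    statistic: float
    p_value: float


# (column, label, kind) - kind selects the test: 'cat' chi-squared,
# 'mean' pooled t (mean (SD) summaries), 'skew' Wilcoxon (median (IQR))
_TABLE_VARIABLES = [
    ("race", "Race, N (%)", "cat"),
    ("hispanic", "Hispanic, N (%)", "cat"),
    ("female", "Female, N (%)", "cat"),
    ("age", "Age (y), Median (IQR)", "skew"),
    ("weight", "Weight (kg), Mean (SD)", "mean"),
    ("height", "Height (cm), Mean (SD)", "mean"),
    ("bmi", "BMI (kg/m^2), Mean (SD)", "mean"),
    ("bodyfat_pct", "Body Fat (%), Mean (SD)", "mean"),
    ("insulin30", "Insulin-30 (uIU/ml), Median (IQR)", "skew"),
    ("tee_baseline_measured", "Baseline TEE (kcal/d), Mean (SD)", "mean"),
    ("ei_measured_start", "Energy intake at start of Test phase (kcal/d), Mean (SD)", "mean"),
    ("runin_loss", "Run-in Percent Weight Loss (%), Mean (SD)", "mean"),
]


def _summarize(x: pd.Series, kind: str) -> str:
    if kind == "mean":
        return f"{x.mean():.1f} ({x.std(ddof=1):.1f})"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def build_baseline_table(
    cohort: pd.DataFrame, grouping: str = "ue_group",
    variables: Sequence[tuple[str, str, str]] | None = None,
) -> list[BaselineComparisonRow]:
    """Compare baseline characteristics between the two *grouping* levels.

    Unknown variables are skipped with a warning row-less; the returned
    rows mirror the layout of a clinical Table 1.
    """
    import warnings

    if grouping not in cohort.columns:
        raise ValueError(
            f"cohort has no {grouping!r} column; run the UE stage first"
        )
    levels = sorted(cohort[grouping].unique())
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {levels}")
    # conventional order: 'low' first when grouping by UE
    if "low" in levels:
        levels = ["low", "high"]
    g_low = cohort[cohort[grouping] == levels[0]]
    g_high = cohort[cohort[grouping] == levels[1]]

    rows: list[BaselineComparisonRow] = []
    for col, label, kind in (variables or _TABLE_VARIABLES):
        if col not in cohort.columns:
            warnings.warn(f"variable {col!r} not in cohort; skipped")
            continue
        if kind == "cat":
            cats = sorted(cohort[col].unique())
            counts = np.array(
                [[(g[col] == c).sum() for g in (g_low, g_high)] for c in cats]
            )
            if counts.shape[0] == 1:  # constant variable: no test possible
                warnings.warn(f"variable {col!r} is constant; skipped")
                continue
            if counts.shape[0] == 2:  # binary: report the positive level
                pos = counts[-1]
                tot = counts.sum(axis=0)
                summ = [
                    f"{p} ({100 * p / t:.1f}%)" for p, t in zip(
                        (pos.sum(), *pos), (tot.sum(), *tot)
                    )
                ]
            else:
                summ = [f"{counts.sum()}", f"{counts[:, 0].sum()}", f"{counts[:, 1].sum()}"]
            try:
                stat, _, p = chi_squared_test(counts)
            except ValueError:
                stat, p = np.nan, np.nan
            rows.append(BaselineComparisonRow(
                label, summ[0], summ[1], summ[2], "chi-squared", stat, p))
        elif kind == "mean":
            t, _, p = pooled_t_test(sample1=g_low[col], sample2=g_high[col])
            rows.append(BaselineComparisonRow(
                label, _summarize(cohort[col], kind),
                _summarize(g_low[col], kind), _summarize(g_high[col], kind),
                "pooled t", t, p))
        else:
            w, p = wilcoxon_rank_sum(g_low[col], g_high[col])
            rows.append(BaselineComparisonRow(
                label, _summarize(cohort[col], kind),
                _summarize(g_low[col], kind), _summarize(g_high[col], kind),
                "Wilcoxon rank sum", w, p))
    return rows


def render_baseline_table(rows: list[BaselineComparisonRow]) -> pd.DataFrame:
    """Rows as a DataFrame with p-values formatted to 4 decimals."""
    return pd.DataFrame(
        {
            "Variable": [r.variable for r in rows],
            "Total": [r.summary_total for r in rows],
            "Low UE": [r.summary_low for r in rows],
            "High UE": [r.summary_high for r in rows],
            "Test": [r.test for r in rows],
            "P value": [f"{r.p_value:.4f}" for r in rows],
        }
    )
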