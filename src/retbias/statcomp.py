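"""Inferential statistics on amplitude tables.

Paired t-tests for within-cell comparisons (first vs second stimulation),
and one-way ANOVA with Tukey's HSD multiple-comparison test across agonist
groups.  Significance stars are a pure threshold function of the adjusted p
value with a configurable ladder (default 0.05 / 0.01 / 0.001 / 0.0001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError

__all__ = [
    "PairedComparison",
    "AnovaTukeyResult",
    "paired_t_test",
    "anova_tukey",
    "significance_stars",
    "DEFAULT_STAR_THRESHOLDS",
]

DEFAULT_STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


@dataclass
class PairedComparison:
    label_x: str
    label_y: str
    n_pairs: int
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    degenerate: bool = False  # zero variance of differences


@dataclass
class AnovaTukeyResult:
    group_labels: list[str]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_unadjusted, p_adjusted, stars


def significance_stars(
    p: float, thresholds=DEFAULT_STAR_THRESHOLDS
) -> str:
    """Map a p value to the star annotation: one star per threshold crossed."""
    if not 0.0 <= p <= 1.0 or np.isnan(p):
        return ""
    stars = 0
    for th in sorted(thresholds, reverse=True):
        if p < th:
            stars += 1
    return "*" * stars if stars else "ns"


def paired_t_test(x, y, label_x: str = "x", label_y: str = "y"
                  ) -> PairedComparison:
    """Classical two-sided paired t-test on x - y.

    Differences with zero variance and a nonzero mean are degenerate: t is
    infinite and p is reported as the limit 0 with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise FitError("paired vectors must have equal length")
    if x.size < 2:
        raise FitError("need >= 2 pairs")
    d = x - y
    n = d.size
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedComparison(label_x, label_y, n, 0.0, 0.0, n - 1, 1.0)
        return PairedComparison(
            label_x, label_y, n, mean_d,
            float(np.sign(mean_d)) * np.inf, n - 1, 0.0, degenerate=True,
        )
    res = stats.ttest_rel(x, y)
    return PairedComparison(
        label_x=label_x,
        label_y=label_y,
        n_pairs=n,
        mean_difference=mean_d,
        t_statistic=float(res.statistic),
        df=n - 1,
        p_value=float(res.pvalue),
    )


def anova_tukey(
    groups: dict[str, np.ndarray],
    star_thresholds=DEFAULT_STAR_THRESHOLDS,
) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    Groups with fewer than 2 observations are excluded with a warning.  The
    pairwise table carries, per pair, the mean difference, the unadjusted p
    (pooled-MSE t-test with N-k degrees of freedom) and the Tukey-adjusted p
    from the studentized-range distribution; adjusted >= unadjusted always.
    """
    usable: dict[str, np.ndarray] = {}
    for label, v in groups.items():
        v = np.asarray(v, dtype=float)
        if v.size < 2:
            warnings.warn(
                f"group {label!r} has n={v.size} < 2; excluded", stacklevel=2
            )
            continue
        usable[label] = v
    if len(usable) < 2:
        raise FitError("need >= 2 groups with n >= 2")
    labels = list(usable)
    arrays = [usable[g] for g in labels]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_between, df_within = k - 1, n_total - k

    grand = np.mean(np.concatenate(arrays))
    ssb = sum(a.size * (np.mean(a) - grand) ** 2 for a in arrays)
    ssw = sum(np.sum((a - np.mean(a)) ** 2) for a in arrays)
    if ssw == 0.0:
        f_stat = 0.0 if ssb == 0.0 else np.inf
        p_overall = 1.0 if ssb == 0.0 else 0.0
    else:
        f_stat = (ssb / df_between) / (ssw / df_within)
        p_overall = float(stats.f.sf(f_stat, df_between, df_within))
    mse = ssw / df_within if df_within > 0 else np.nan

    tukey = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(np.mean(arrays[i]) - np.mean(arrays[j]))
            se = np.sqrt(mse * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            if se > 0:
                t_val = diff / se
                p_unadj = float(2.0 * stats.t.sf(abs(t_val), df_within))
            else:
                p_unadj = 1.0 if diff == 0.0 else 0.0
            p_adj = float(tukey.pvalue[i, j])
            if np.isnan(p_adj):  # zero pooled variance degenerate case
                p_adj = 1.0 if diff == 0.0 else 0.0
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": diff,
                    "p_unadjusted": p_unadj,
                    "p_adjusted": p_adj,
                    "stars": significance_stars(p_adj, star_thresholds),
                }
            )
    return AnovaTukeyResult(
        group_labels=labels,
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p_overall,
        pairwise=pd.DataFrame(rows),
    )
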