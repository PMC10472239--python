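"""Cohort statistics: group summaries, one-way ANOVA with Tukey HSD, t test,
linear correlation.

Classical (non-Welch) procedures, matching how grouped mouse measurements
are conventionally compared: one-way ANOVA with Tukey's multiple-comparison
test performed only when the omnibus test is significant, plain two-sample
t tests (two-sided), and squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    mean: float
    sd: float | None      # n-1 sample SD; None for a single value
    sem: float | None
    n: int


@dataclass
class TukeyComparison:
    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    tukey: list[TukeyComparison] | None   # None when the omnibus test was
    #                                       not significant (not performed)


def summarize(values) -> GroupSummary:
    """Mean, sample SD (n-1), SEM and n for one group."""
    x = np.asarray(list(values), dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    if x.size == 1:
        return GroupSummary(mean=float(x[0]), sd=None, sem=None, n=1)
    sd = float(x.std(ddof=1))
    return GroupSummary(mean=float(x.mean()), sd=sd,
                        sem=sd / np.sqrt(x.size), n=int(x.size))


def two_sample_t(a, b) -> tuple[float, float]:
    """Plain (pooled-variance, two-sided) two-sample t test."""
    t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                         equal_var=True)
    return float(t), float(p)


def one_way_anova_tukey(groups: dict[str, list[float]],
                        alpha: float = 0.05,
                        force_tukey: bool = False) -> AnovaResult:
    """One-way ANOVA; Tukey HSD pairwise comparisons when significant.

    ``groups`` maps label -> measurements (>= 2 groups, each n >= 2).
    Tukey comparisons are computed only when the omnibus p < alpha, unless
    ``force_tukey``; otherwise the ``tukey`` slot is None (not performed).
    With zero variance everywhere and equal means, F is reported as 0.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=np.float64) for g in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")

    if all(a.std() == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*arrays)
        f, p = float(f), float(p)

    tukey = None
    if (p < alpha or force_tukey) and np.isfinite(f):
        res = sps.tukey_hsd(*arrays)
        tukey = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                tukey.append(TukeyComparison(
                    group_a=labels[i], group_b=labels[j],
                    mean_difference=float(arrays[i].mean() - arrays[j].mean()),
                    p_adjusted=float(res.pvalue[i, j])))
    return AnovaResult(f_statistic=f, p_value=p, tukey=tukey)


def linear_r2(x, y) -> float:
    """Squared Pearson correlation of paired measurements."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant series")
    r, _ = sps.pearsonr(x, y)
    return float(r * r)
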