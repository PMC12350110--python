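"""Comparison statistics and normality diagnostics for the quantifications.

Two-group comparisons use the classical equal-variance Student t-test
(Welch's correction is available behind a flag); three or more groups use
one-way ANOVA with post-hoc Tukey HSD adjusted pairwise p-values.  The
significance convention maps stars to thresholds 0.05, 0.01, 0.001, 0.0001.
Normality is screened with a normal quantile-quantile plot at plotting
positions (i − 0.5)/n and its correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class StatResult:
    design: str                       # "two_group" | "multi_group"
    statistic: float                  # t for two groups, F otherwise
    p_value: float
    pairwise: list[dict] | None = None  # Tukey: {"pair", "p_adj"}

    @property
    def stars(self) -> str:
        return star_notation(self.p_value)


def star_notation(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p <= thr:
            return s
    return "ns"


def compare_groups(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    welch: bool = False,
) -> StatResult:
    """Compare numeric samples: Student t for 2 groups, ANOVA+Tukey for ≥3.

    Degenerate inputs are handled deterministically: identical groups give
    t = 0 (or F = 0) with p = 1 instead of a 0/0 NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    if labels is None:
        labels = [f"group{i+1}" for i in range(len(arrays))]
    if len(arrays) == 2:
        a, b = arrays
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if a.mean() == b.mean():
                return StatResult("two_group", 0.0, 1.0)
            return StatResult("two_group", float("inf") * np.sign(a.mean() - b.mean()), 0.0)
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        return StatResult("two_group", float(t), float(p))
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        raise ValueError("zero variance in all groups; comparison undefined")
    means = np.array([a.mean() for a in arrays])
    if all(a.var(ddof=1) == 0 for a in arrays) and np.ptp(means) == 0:
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*arrays)
    group_codes = np.concatenate([[labels[i]] * arrays[i].size for i in range(len(arrays))])
    tukey = pairwise_tukeyhsd(grand, group_codes, alpha=0.05)
    rows = tukey.summary().data[1:]   # group1, group2, meandiff, p-adj, ...
    pairwise = [{"pair": (str(r[0]), str(r[1])), "p_adj": float(p_)}
                for r, p_ in zip(rows, tukey.pvalues)]
    return StatResult("multi_group", float(f), float(p), pairwise)


def qq_points(sample: Sequence[float]) -> tuple[np.ndarray, float]:
    """Normal QQ pairs and their correlation coefficient.

    Theoretical quantiles are standard-normal at plotting positions
    (i − 0.5)/n; the empirical quantiles are the order statistics.  Returns
    ``(pairs, r)`` where ``pairs`` is an (n, 2) array of (theoretical,
    empirical) values.  A constant sample has no ordering information and is
    an error.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("QQ analysis needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: QQ correlation undefined")
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    r = float(np.corrcoef(theo, x)[0, 1])
    return np.column_stack([theo, x]), r
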