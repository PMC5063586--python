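"""Statistical layer: one-way ANOVA, Holm-Bonferroni step-down, two-group
t-test and box summaries.

ANOVA and Holm are implemented directly from their defining formulas (only
the F / t tail probabilities come from scipy's distribution functions) so
the test suite can check them against brute-force oracles.  Quartiles use
linear interpolation between closest ranks, the default convention of the
statistics environments used at the bench.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "AnovaResult",
    "MultCompResult",
    "BoxSummary",
    "one_way_anova",
    "holm_bonferroni",
    "two_group_ttest",
    "box_summary",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    defined: bool = True


@dataclass
class MultCompResult:
    """Holm step-down decisions, ordered by ascending raw p-value."""

    order: np.ndarray          # indices into the input p-value vector
    pvals: np.ndarray          # sorted raw p-values
    thresholds: np.ndarray     # alpha / (m - i) for sorted position i
    reject: np.ndarray         # boolean, a prefix of the sorted list
    alpha: float

    def rejected_indices(self) -> np.ndarray:
        return self.order[self.reject]


@dataclass
class BoxSummary:
    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: list = field(default_factory=list)


def one_way_anova(groups) -> AnovaResult:
    """Standard between/within sum-of-squares decomposition.

    ``groups`` is a sequence of 1-D value vectors, one per group.  With zero
    within-group variance and equal means the F ratio is undefined and the
    result is flagged.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = n_total - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(float("nan"), df_b, df_w, float("nan"), defined=False)
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(_sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p)


def holm_bonferroni(pvals, alpha: float = 0.05) -> MultCompResult:
    """Holm's step-down procedure: reject the i-th smallest p-value while
    p(i) <= alpha / (m - i + 1), stopping at the first failure."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    m = len(ps)
    thresholds = alpha / (m - np.arange(m))
    reject = np.zeros(m, dtype=bool)
    for i in range(m):
        if ps[i] <= thresholds[i]:
            reject[i] = True
        else:
            break
    return MultCompResult(
        order=order, pvals=ps, thresholds=thresholds, reject=reject, alpha=alpha
    )


def two_group_ttest(a, b) -> tuple:
    """Unpaired two-sided Student t-test (pooled variance).  Returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    if sp2 == 0:
        return (float("inf") if a.mean() != b.mean() else float("nan"), 0.0)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = float(2 * _sps.t.sf(abs(t), na + nb - 2))
    return float(t), p


def box_summary(values) -> BoxSummary:
    """Quartiles with whiskers at the most extreme data points within
    1.5 x IQR of the box; points beyond the whiskers are outliers."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_lo = float(inside.min()) if inside.size else float(q1)
    whisker_hi = float(inside.max()) if inside.size else float(q3)
    outliers = sorted(v[(v < lo_fence) | (v > hi_fence)].tolist())
    return BoxSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_lo=whisker_lo,
        whisker_hi=whisker_hi,
        outliers=outliers,
    )
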