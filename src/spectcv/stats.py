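"""Group-level statistics for AUC(CV_T) scores.

Thin wrappers over :mod:`scipy.stats`: a two-tailed Mann-Whitney U
comparison (exact for small tie-free designs, tie-corrected normal
approximation otherwise) and mean +/- 95% CI summaries with the
Student-t convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError

__all__ = ["GroupComparison", "GroupSummary", "mann_whitney_u", "group_summary"]


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    ci95_half_width: float | None

    def __str__(self):
        ci = "n/a" if self.ci95_half_width is None else f"{self.ci95_half_width:.1f}"
        return f"n={self.n} mean={self.mean:.1f} sd={self.sd:.1f} ci95=+/-{ci}"


@dataclass
class GroupComparison:
    n1: int
    n2: int
    u_statistic: float
    p_two_tailed: float
    method: str
    group_a: GroupSummary
    group_b: GroupSummary

    def __str__(self):
        return (
            f"Mann-Whitney U={self.u_statistic:g} ({self.method}), "
            f"two-tailed p={self.p_two_tailed:.4g}\n"
            f"  A: {self.group_a}\n  B: {self.group_b}"
        )


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Mean, sample SD and t-based 95% CI half-width of one group.

    The CI half-width is ``t(0.975, n-1) * SD / sqrt(n)``; undefined
    (None) for n < 2.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("group must be non-empty")
    mean = float(v.mean())
    if v.size < 2:
        return GroupSummary(v.size, mean, float("nan"), None)
    sd = float(v.std(ddof=1))
    half = float(sps.t.ppf(0.975, v.size - 1) * sd / np.sqrt(v.size))
    return GroupSummary(v.size, mean, sd, half)


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupComparison:
    """Two-tailed Mann-Whitney U test between two groups of scores.

    The exact null distribution is used when ``n1 * n2 <= 400`` and no
    value is shared *between* the groups (within-group ties leave the
    rank-sum enumeration intact); otherwise the tie-corrected normal
    approximation with continuity correction is used.  ``u_statistic`` is
    reported for ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    cross_ties = bool(np.intersect1d(a, b).size)
    exact = a.size * b.size <= 400 and not cross_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        n1=a.size,
        n2=b.size,
        u_statistic=float(res.statistic),
        p_two_tailed=float(min(res.pvalue, 1.0)),
        method=method,
        group_a=group_summary(a),
        group_b=group_summary(b),
    )
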