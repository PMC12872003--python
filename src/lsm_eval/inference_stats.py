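"""Small-sample inference: exact Mann-Whitney U and Pearson chi-square.

With four sub-districts per arm, the rank-sum comparison must be exact:
the two-sided p-value is obtained by full enumeration of all
C(n1+n2, n1) equally-likely group assignments of the pooled mid-ranks,
not from the normal approximation (whose continuity-corrected defaults
disagree at these sizes). Complete separation of 4 vs 4 gives the
smallest attainable two-sided p, 2/70 ~ 0.029.

The contingency-table comparison is the plain Pearson chi-square without
continuity correction, with expected counts from the product of margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "RankSumMethod",
    "RankSumResult",
    "ChiSquareResult",
    "mann_whitney_exact",
    "chi_square_test",
    "confusion_metrics",
]

#: group sizes up to this pooled total are enumerated exactly
EXACT_ENUMERATION_LIMIT = 20


class RankSumMethod(str, Enum):
    exact = "exact"
    normal_approx = "normal_approx"


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float  # min(U_a, U_b)
    p_two_sided: float
    n1: int
    n2: int
    method: RankSumMethod

    def __post_init__(self):
        if not 0 <= self.u_statistic <= self.n1 * self.n2:
            raise ValueError("U must lie in [0, n1*n2]")
        if not 0 < self.p_two_sided <= 1:
            raise ValueError("p must lie in (0, 1]")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def mann_whitney_exact(group_a, group_b) -> RankSumResult:
    """Two-sample Mann-Whitney U with an exact two-sided p-value.

    U is reported as min(U_a, U_b) with mid-ranks for ties. For pooled
    sizes up to 20 the p-value is exact: every assignment of the pooled
    mid-ranks to the groups is enumerated and
    ``p = min(1, 2 * min(P(U_a <= u), P(U_a >= u)))``. Larger samples
    fall back to the tie-corrected normal approximation without
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r_a = ranks[:n1].sum()
    u_a = r_a - n1 * (n1 + 1) / 2.0
    u_b = n1 * n2 - u_a

    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        # enumerate U_a over all C(n, n1) assignments of the mid-ranks
        idx = range(n1 + n2)
        base = n1 * (n1 + 1) / 2.0
        us = np.fromiter(
            (ranks[list(c)].sum() - base for c in combinations(idx, n1)),
            dtype=float,
        )
        eps = 1e-9
        lower = np.mean(us <= u_a + eps)
        upper = np.mean(us >= u_a - eps)
        p = min(1.0, 2.0 * min(lower, upper))
        method = RankSumMethod.exact
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        p = float(res.pvalue)
        method = RankSumMethod.normal_approx

    return RankSumResult(
        u_statistic=float(min(u_a, u_b)),
        p_two_sided=float(p),
        n1=int(n1),
        n2=int(n2),
        method=method,
    )


def chi_square_test(table) -> ChiSquareResult:
    """Pearson chi-square on an r x c count table, no continuity correction.

    Expected counts are row_total * col_total / grand_total; a zero row
    or column margin leaves them undefined and raises.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("every row and column margin must be positive")
    statistic, p, df, expected = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(
        statistic=float(statistic), df=int(df), p_value=float(p),
        expected=np.asarray(expected),
    )


def confusion_metrics(tp: int, fp: int, fn: int, tn: int):
    """Accuracy, precision and recall from confusion counts.

    Precision (recall) is NaN when its denominator tp+fp (tp+fn) is
    zero — reported as missing rather than forced to 0 or 1.
    """
    counts = (tp, fp, fn, tn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    return accuracy, precision, recall
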