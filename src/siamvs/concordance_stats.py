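"""Method-ranking statistics: Kendall's coefficient of concordance.

Activity classes act as judges, screening methods as the objects being
ranked by their recall.  Within each judge's row the largest recall
receives the highest rank (n), ties receive mid-ranks, and the
concordance

    W = 12 * sum_i (R_i - Rbar)^2 / (m^2 (n^3 - n) - m * sum_j T_j)

measures agreement across the m judges (W = 1: identical rankings;
W = 0: no agreement), with the standard tie-correction term
``T_j = sum (t^3 - t)`` over tie groups of judge j.  Significance uses
the chi-square approximation ``chi2 = m (n - 1) W`` on ``n - 1``
degrees of freedom.

The improvement percentage between two methods' recall values,
``100 * (r1 - r2) / r1``, quantifies head-to-head gains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, rankdata

__all__ = [
    "ConcordanceResult",
    "rank_within_judge",
    "kendall_w",
    "improvement_percentage",
    "rank_report",
]


@dataclass(frozen=True)
class ConcordanceResult:
    """Kendall-W outcome for one judge matrix."""

    w: float
    mean_ranks: np.ndarray
    total_ranks: np.ndarray
    chi_square: float
    p_value: float
    n_judges: int
    n_objects: int

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_value < 0.01


def rank_within_judge(row) -> np.ndarray:
    """Mid-ranks of one judge's scores, largest score -> rank n."""
    row = np.asarray(row, dtype=np.float64)
    if row.size == 0:
        raise ValueError("empty score row")
    if not np.isfinite(row).all():
        raise ValueError("non-finite score in judge row")
    return rankdata(row)


def kendall_w(matrix, tie_correction: bool = True) -> ConcordanceResult:
    """Kendall's W of an ``(m judges, n objects)`` score matrix.

    ``tie_correction=False`` uses the plain denominator
    ``m^2 (n^3 - n)``; the two agree on tie-free matrices.
    """
    M = np.asarray(matrix, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a matrix with >= 2 judges and >= 2 objects")
    if not np.isfinite(M).all():
        raise ValueError("non-finite entry in judge matrix")
    m, n = M.shape
    R = np.vstack([rank_within_judge(row) for row in M])
    total = R.sum(axis=0)
    grand_mean = 0.5 * m * (n + 1)
    delta = float(((total - grand_mean) ** 2).sum())
    denom = m * m * (n**3 - n)
    if tie_correction:
        T = 0.0
        for row in R:
            _, counts = np.unique(row, return_counts=True)
            T += float((counts.astype(np.float64) ** 3 - counts).sum())
        denom -= m * T
    if denom <= 0:
        # every judge ranks everything tied: no information
        raise ValueError("degenerate matrix: all ranks tied within judges")
    w = 12.0 * delta / denom
    chi_sq = m * (n - 1) * w
    return ConcordanceResult(
        w=float(w),
        mean_ranks=total / m,
        total_ranks=total,
        chi_square=float(chi_sq),
        p_value=float(chi2.sf(chi_sq, n - 1)),
        n_judges=m,
        n_objects=n,
    )


def improvement_percentage(recall_1: float, recall_2: float) -> float:
    """Percentage improvement of method 1 over method 2.

    ``100 * (recall_1 - recall_2) / recall_1``; positive when method 1
    is better.
    """
    if recall_1 <= 0:
        raise ValueError("recall of the reference method must be positive")
    return 100.0 * (recall_1 - recall_2) / recall_1


def rank_report(matrix, method_names) -> list[tuple[str, float]]:
    """Methods ordered by descending mean rank (ties keep input order)."""
    M = np.asarray(matrix, dtype=np.float64)
    names = list(method_names)
    if M.ndim != 2 or M.shape[1] != len(names):
        raise ValueError("method-name count does not match matrix columns")
    # mean ranks directly, so fully tied tables still yield a report
    R = np.vstack([rank_within_judge(row) for row in M])
    mean_ranks = R.mean(axis=0)
    order = sorted(range(len(names)), key=lambda j: (-mean_ranks[j], j))
    return [(names[j], float(mean_ranks[j])) for j in order]
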