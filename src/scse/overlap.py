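"""Interval-set overlap statistics: hypergeometric enrichment, overlap
percentages, signal comparison and base-pair Jaccard similarity.

The hypergeometric universe ``N`` is the number of maximal merged
regions in the base-pair union of both interval sets.  Both the point
mass at ``k`` and the upper tail ``P(X >= k)`` are reported; the tail is
the significance used for enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import merge_intervals, overlap_pairs
from .io import GenomicInterval

__all__ = ["OverlapTestResult", "interval_overlap_count",
           "union_region_count", "hypergeometric_test", "overlap_percent",
           "signal_compare", "jaccard", "overlap_report"]


@dataclass
class OverlapTestResult:
    N: int
    K: int
    n: int
    k: int
    p_point: float
    p_tail: float
    percent_query: float | None = None
    percent_ref: float | None = None


def interval_overlap_count(query: Sequence[GenomicInterval],
                           reference: Sequence[GenomicInterval],
                           min_bp: int = 1
                           ) -> tuple[int, int, list[tuple[int, int]]]:
    """(number of query intervals hit, reference intervals hit, pairs)."""
    pairs = overlap_pairs(query, reference, min_bp)
    k_query = len({i for i, _ in pairs})
    k_ref = len({j for _, j in pairs})
    return k_query, k_ref, pairs


def union_region_count(set_a: Sequence[GenomicInterval],
                       set_b: Sequence[GenomicInterval]) -> int:
    """Number of maximal merged regions in the bp-union of both sets."""
    both = list(set_a) + list(set_b)
    if not both:
        return 0
    return len(merge_intervals(both))


def hypergeometric_test(N: int, K: int, n: int, k: int,
                        k_ref: int | None = None) -> OverlapTestResult:
    """Hypergeometric overlap significance.

    ``p_point`` is the mass C(K,k) C(N-K,n-k) / C(N,n); ``p_tail`` is
    P(X >= k), computed in log space by scipy for large arguments.
    """
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n={n}, K={K})")
    if n > N or K > N:
        raise ValueError(f"n={n} and K={K} must not exceed N={N}")
    if n - k > N - K:
        raise ValueError(f"infeasible counts: n-k={n - k} > N-K={N - K}")
    dist = stats.hypergeom(N, K, n)
    p_point = float(dist.pmf(k))
    p_tail = float(dist.sf(k - 1))
    pct_q = overlap_percent(k, n) if n > 0 else None
    pct_r = overlap_percent(k_ref, K) if (k_ref is not None and K > 0) else None
    return OverlapTestResult(N, K, n, k, p_point, min(p_tail, 1.0),
                             pct_q, pct_r)


def overlap_percent(k: int, n: int) -> float:
    """100 * k / n with half-up rounding to two decimals."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    pct = Decimal(100) * Decimal(k) / Decimal(n)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def signal_compare(overlapping: Sequence[float],
                   nonoverlapping: Sequence[float],
                   equal_var: bool = False) -> tuple[float, float]:
    """log2 fold change of group means and a two-sided two-sample t-test p.

    Welch's unequal-variance test by default.  A zero denominator mean is
    guarded with a small epsilon and a warning; two constant groups give
    p = 1 when equal, 0 otherwise.
    """
    a = np.asarray(overlapping, dtype=float)
    b = np.asarray(nonoverlapping, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    mb = b.mean()
    if mb == 0:
        warnings.warn("nonoverlapping mean is zero; epsilon-guarded")
        mb = np.finfo(float).eps
    l2fc = float(np.log2(a.mean() / mb)) if a.mean() > 0 else float("-inf")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return l2fc, p


def jaccard(set_a: Sequence[GenomicInterval],
            set_b: Sequence[GenomicInterval]) -> float:
    """Base-pair Jaccard of the merged interval sets."""
    if not set_a and not set_b:
        warnings.warn("jaccard of two empty sets defined as 0")
        return 0.0
    a = merge_intervals(set_a) if set_a else []
    b = merge_intervals(set_b) if set_b else []
    inter = 0
    for i, j in overlap_pairs(a, b):
        inter += min(a[i].end, b[j].end) - max(a[i].start, b[j].start)
    bp = lambda ivs: sum(len(iv) for iv in ivs)
    union = bp(a) + bp(b) - inter
    return inter / union if union else 0.0


def overlap_report(query: Sequence[GenomicInterval],
                   reference: Sequence[GenomicInterval],
                   min_bp: int = 1) -> tuple[OverlapTestResult, float]:
    """End-to-end overlap test between two interval sets.

    Returns the hypergeometric result (with both overlap percentages)
    and the bp Jaccard coefficient.
    """
    k_query, k_ref, _ = interval_overlap_count(query, reference, min_bp)
    N = union_region_count(query, reference)
    res = hypergeometric_test(N, len(reference), len(query), k_query,
                              k_ref=k_ref)
    return res, jaccard(query, reference)
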