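"""Data-driven derivation of R-score ordinals from replication counts.

Where should the low/medium and medium/high replication thresholds sit, and
how many ordinals should there be at all?  Rather than letting any individual
decide, this module mines a corpus of per-phenomenon replication counts:
cluster the counts, use the number of clusters as the number of ordinals, and
place the category thresholds between adjacent clusters.

Clustering is an **exact** 1-D dynamic program minimising within-cluster sum
of squares (in one dimension the optimal partition is contiguous on the
sorted values, so the global optimum is computable — no Lloyd-style restarts,
no initialisation arbitrariness).  The number of clusters can be chosen
automatically by a Gaussian model-selection score: per-cluster means with a
shared variance estimate, penalised by parameter count times log n (the
criterion behind x-means-style cluster-count selection).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CalibrationResult",
    "cluster_1d",
    "select_k",
    "calibrate_r_scale",
    "score_r_from_thresholds",
]


@dataclass
class CalibrationResult:
    """An optimal 1-D clustering and the ordinal thresholds it implies.

    ``boundaries`` has ``k - 1`` ascending entries, each the midpoint between
    the maximum of one cluster and the minimum of the next; a count equal to
    a boundary belongs to the *upper* ordinal (half-open convention).
    ``assignments`` maps every distinct input value to its cluster index
    (0 = lowest cluster) and is monotone in the value.
    """

    k: int
    boundaries: list[float]
    assignments: dict[float, int]
    within_ss: float
    selection_scores: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "boundaries": self.boundaries,
            "assignments": {str(v): c for v, c in self.assignments.items()},
            "within_ss": self.within_ss,
            "selection_scores": {str(k): s for k, s in self.selection_scores.items()},
        }


def _dp_partition(x: np.ndarray, k: int) -> tuple[list[np.ndarray], float]:
    """Optimal contiguous k-partition of sorted x by within-SS (exact DP).

    Vectorised O(k n^2) dynamic program over the full segment-cost matrix.
    Returns the clusters (as arrays) and the total within-cluster SS.
    """
    n = x.size
    # cost[j, i]: within-SS of segment x[j..i] inclusive (inf for j > i)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    j_idx = np.arange(n)[:, None]
    i_idx = np.arange(n)[None, :]
    cnt = i_idx - j_idx + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        seg_sum = s1[i_idx + 1] - s1[j_idx]
        seg_sq = s2[i_idx + 1] - s2[j_idx]
        cost = seg_sq - seg_sum**2 / cnt
    cost[cnt < 1] = np.inf
    cost = np.maximum(cost, 0.0)  # clamp tiny negative round-off

    # D[m, i]: best cost of splitting x[0..i] into m+1 clusters
    D = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=int)
    D[0] = cost[0]
    for m in range(1, k):
        # candidate start j of the last cluster: D[m-1, j-1] + cost[j, i]
        prev = np.concatenate([[np.inf], D[m - 1, :-1]])
        total = prev[:, None] + cost
        split[m] = np.argmin(total, axis=0)
        D[m] = total[split[m], np.arange(n)]

    # backtrack cluster boundaries
    bounds: list[int] = []
    i = n - 1
    for m in range(k - 1, 0, -1):
        j = int(split[m, i])
        bounds.append(j)
        i = j - 1
    bounds.reverse()
    clusters = [arr for arr in np.split(x, bounds)]
    return clusters, float(D[k - 1, n - 1])


def cluster_1d(values: Sequence[float], k: int) -> CalibrationResult:
    """Globally optimal k-clustering of 1-D values by within-cluster SS.

    Deterministic and exact (dynamic programming over the sorted order).
    ``k`` may not exceed the number of distinct values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(x).size
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct value(s)")

    clusters, wss = _dp_partition(x, k)
    boundaries = [
        float((clusters[j][-1] + clusters[j + 1][0]) / 2.0) for j in range(k - 1)
    ]
    assignments: dict[float, int] = {}
    for ci, cl in enumerate(clusters):
        for v in cl:
            assignments[float(v)] = ci
    return CalibrationResult(
        k=k, boundaries=boundaries, assignments=assignments, within_ss=wss
    )


def _gaussian_score(x: np.ndarray, k: int) -> float:
    """BIC-style selection score for the k-cluster Gaussian model (lower = better).

    Uses per-cluster means, mixing proportions, and a shared variance
    estimated as within-SS / (n - k); the penalty is the parameter count
    (k means + k-1 proportions + 1 variance = 2k) times log n.
    """
    n = x.size
    clusters, wss = _dp_partition(x, k)
    if n - k <= 0 or wss <= 0:
        # Degenerate: every cluster is a single distinct value.  Floor the
        # variance at a scale-proportional epsilon so the score stays finite.
        span = float(x.max() - x.min())
        sigma2 = max(span * 1e-9, 1e-12) ** 2
    else:
        sigma2 = wss / (n - k)
    loglik = 0.0
    for cl in clusters:
        loglik += cl.size * np.log(cl.size / n)
    loglik += -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * (n - k)
    n_params = 2 * k
    return float(-2.0 * loglik + n_params * np.log(n))


def select_k(
    values: Sequence[float], k_range: Sequence[int] | range
) -> tuple[int, dict[int, float]]:
    """Choose the cluster count minimising the Gaussian selection score.

    Returns ``(best_k, scores)`` with the score of every candidate recorded.
    Candidates exceeding the distinct-value count are invalid.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("values must be non-empty")
    n_distinct = np.unique(x).size
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    if ks[0] < 1 or ks[-1] > n_distinct:
        raise ValueError(
            f"k_range must lie within [1, {n_distinct}] (distinct-value count)"
        )
    if n_distinct == 1:
        return 1, {1: _gaussian_score(x, 1)}
    scores = {k: _gaussian_score(x, k) for k in ks}
    best = min(scores, key=lambda k: (scores[k], k))
    return best, scores


def calibrate_r_scale(
    values: Sequence[float],
    k: int | None = None,
    k_range: Sequence[int] | range | None = None,
) -> CalibrationResult:
    """Full calibration: optionally select k, then cluster and set thresholds.

    Exactly one of ``k`` and ``k_range`` must be given.
    """
    if (k is None) == (k_range is None):
        raise ValueError("give exactly one of k or k_range")
    scores: dict[int, float] = {}
    if k is None:
        k, scores = select_k(values, k_range)
    result = cluster_1d(values, k)
    result.selection_scores = scores
    return result


def score_r_from_thresholds(
    replication_count: float,
    result: CalibrationResult,
    labels: Sequence[str],
) -> str:
    """Map a replication count to its R-score ordinal label.

    ``labels`` run lowest to highest and must match the cluster count.  A
    count equal to a threshold falls in the upper ordinal.
    """
    if len(labels) != result.k:
        raise ValueError(
            f"{len(labels)} labels for {result.k} clusters; counts must match"
        )
    # bisect_right sends a count equal to a threshold to the upper ordinal,
    # i.e. the half-open convention.
    idx = bisect.bisect_right(result.boundaries, replication_count)
    return labels[idx]
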