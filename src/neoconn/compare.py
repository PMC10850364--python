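"""Cross-modal map comparison: Euclidean and Jaccard distances, similarity maps.

Both distances act on the full sparsified adjacency matrices, summing over
all ordered off-diagonal entries (each unordered connection counted twice;
absent connections contribute weight 0):

    d_E = sqrt( sum_ij (a1_ij - a2_ij)^2 )
    d_J = 1 - J,  J = sum_ij min(a1_ij, a2_ij) / sum_ij max(a1_ij, a2_ij)
          when the denominator is positive, else J = 1 (two empty maps are
          identical, d_J = 0).

For binarized maps d_J reduces to one minus the Jaccard index of the two
edge sets.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats as _st

from .connectivity import ConnectivityMap, SparsifiedMap, sparsify
from .exceptions import ComparisonError, DimensionError

#: sparsity grid spanning the comparison range
DEFAULT_COMPARISON_GRID: Tuple[float, ...] = tuple(
    np.round(np.arange(0.20, 0.461, 0.02), 2)
)


def euclidean_distance(a1: SparsifiedMap, a2: SparsifiedMap) -> float:
    a1.compatible_with(a2)
    d = a1.adjacency() - a2.adjacency()
    return float(np.sqrt((d * d).sum()))


def jaccard_distance(a1: SparsifiedMap, a2: SparsifiedMap) -> float:
    a1.compatible_with(a2)
    m1, m2 = a1.adjacency(), a2.adjacency()
    if (m1 < 0).any() or (m2 < 0).any():
        raise ComparisonError("Jaccard distance requires nonnegative retained weights")
    s_max = np.maximum(m1, m2).sum()
    if s_max <= 0:
        return 0.0  # both maps empty: J = 1, d_J = 0
    s_min = np.minimum(m1, m2).sum()
    return float(1.0 - s_min / s_max)

_METRICS = {"euclidean": euclidean_distance, "jaccard": jaccard_distance}


@dataclass
class DistanceProfile:
    """Per-sparsity mean / SD / 95% CI of subject-by-subject map distances."""

    sparsity_grid: Tuple[float, ...]
    mean: np.ndarray
    sd: np.ndarray
    ci95: np.ndarray  # (len(grid), 2)
    metric: str
    weighted: bool
    n_pairs: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sparsity": self.sparsity_grid,
                "metric": self.metric,
                "weighted": self.weighted,
                "mean": self.mean,
                "sd": self.sd,
                "ci_lo": self.ci95[:, 0],
                "ci_hi": self.ci95[:, 1],
            }
        )


def pair_distance(
    map_a: ConnectivityMap, map_b: ConnectivityMap, sparsity: float, metric: str, weighted: bool
) -> float:
    """Distance between one subject's two maps after sparsifying both."""
    sa = sparsify(map_a, sparsity, binarized=not weighted)
    sb = sparsify(map_b, sparsity, binarized=not weighted)
    return _METRICS[metric](sa, sb)


def distance_profile(
    pairs: Sequence[Tuple[ConnectivityMap, ConnectivityMap]],
    grid: Sequence[float] = DEFAULT_COMPARISON_GRID,
    metric: str = "jaccard",
    weighted: bool = False,
) -> DistanceProfile:
    """Aggregate subject-by-subject cross-modal distances over a sparsity grid.

    The 95% CI is the t-interval on the per-subject distances at each grid
    point.
    """
    if metric not in _METRICS:
        raise ComparisonError(f"unknown metric {metric!r}")
    if len(pairs) == 0:
        raise ComparisonError("empty pair list")
    grid = tuple(grid)
    if any(g2 <= g1 for g1, g2 in zip(grid, grid[1:])):
        raise ComparisonError("sparsity grid must be strictly increasing")
    n = len(pairs)
    means, sds, cis = [], [], []
    for s in grid:
        d = np.array([pair_distance(a, b, s, metric, weighted) for a, b in pairs])
        m, sd = d.mean(), d.std(ddof=1) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = _st.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        else:
            half = 0.0
        means.append(m)
        sds.append(sd)
        cis.append((m - half, m + half))
    return DistanceProfile(
        grid, np.array(means), np.array(sds), np.array(cis), metric, weighted, n
    )


@dataclass
class SimilarityMap:
    """Connection-wise cross-modal agreement over a cohort.

    ``weighted_avg_euclidean``: entry (i, j) is the mean over subjects of
    |a1_ij - a2_ij| (the per-connection Euclidean distance; lower = more
    similar). ``binarized_shared_fraction``: the fraction of subjects for
    whom the connection is retained in both modalities (higher = more
    similar).
    """

    values: np.ndarray
    node_labels: Tuple[str, ...]
    mode: str
    n_subjects: int


def similarity_map(
    cohort_a: Sequence[SparsifiedMap],
    cohort_b: Sequence[SparsifiedMap],
    mode: str = "binarized_shared_fraction",
) -> SimilarityMap:
    """Cohort-level similarity map between two modalities (subjects paired by index)."""
    if mode not in ("weighted_avg_euclidean", "binarized_shared_fraction"):
        raise ComparisonError(f"unknown similarity mode {mode!r}")
    if len(cohort_a) != len(cohort_b) or len(cohort_a) == 0:
        raise ComparisonError("cohorts must be nonempty and paired by subject")
    labels = cohort_a[0].node_labels
    n = len(labels)
    acc = np.zeros((n, n))
    for sa, sb in zip(cohort_a, cohort_b):
        sa.compatible_with(sb)
        if sa.node_labels != labels:
            raise ComparisonError("inconsistent node labels across the cohort")
        ma, mb = sa.adjacency(), sb.adjacency()
        if mode == "weighted_avg_euclidean":
            acc += np.abs(ma - mb)
        else:
            acc += ((ma != 0) & (mb != 0)).astype(float)
    return SimilarityMap(acc / len(cohort_a), labels, mode, len(cohort_a))
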