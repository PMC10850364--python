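"""Pearson-correlation connectivity maps and proportional sparsification.

A resting-state functional-connectivity (RSFC) map is the node x node matrix
of Pearson correlations between channel (20x20) or lobe (8x8) time series.
Sparsification keeps the strongest positive connections: negative and zero
weights are discarded first, then the top ``floor(s * N(N-1)/2)`` edges are
retained, where ``s`` is the sparsity level. Weighted maps keep the original
correlations; binarized maps round retained connections to 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import FrozenSet, Sequence, Tuple

import numpy as np

from .exceptions import ComparisonError, ConfigurationError, DegenerateDataError, DimensionError
from .recording import TimeSeriesRecording

logger = logging.getLogger(__name__)

Edge = Tuple[int, int]  # (i, j) with i < j


@dataclass
class ConnectivityMap:
    """Symmetric node x node Pearson correlation matrix with labels."""

    weights: np.ndarray
    node_labels: Tuple[str, ...]
    signal_type: str = ""
    subject_id: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DimensionError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] != len(self.node_labels):
            raise DimensionError("node_labels length must match matrix size")
        if not np.all(np.isfinite(w)):
            raise DegenerateDataError("weights contain non-finite entries")
        if not np.allclose(w, w.T, atol=1e-12):
            raise DimensionError("weights must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 1.0)
        self.weights = w
        self.node_labels = tuple(self.node_labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def correlation_map(rec: TimeSeriesRecording) -> ConnectivityMap:
    """Pearson correlation between all row pairs of a recording."""
    data = rec.data
    if data.ndim != 2:
        raise DimensionError("correlation_map needs a 2-D (channels x times) recording")
    if data.shape[1] < 3:
        raise DegenerateDataError("need at least 3 time points for correlation")
    constant = np.flatnonzero(np.ptp(data, axis=1) == 0)
    if constant.size:
        names = ", ".join(rec.channel_names[i] for i in constant)
        raise DegenerateDataError(f"constant channel(s): {names}; correlation undefined")
    w = np.corrcoef(data)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return ConnectivityMap(w, rec.channel_names, rec.modality, rec.subject_id)


@dataclass
class SparsifiedMap:
    """A connectivity map thresholded to its strongest positive edges."""

    base: ConnectivityMap
    sparsity: float
    binarized: bool
    retained: FrozenSet[Edge]

    @property
    def n_nodes(self) -> int:
        return self.base.n_nodes

    @property
    def node_labels(self) -> Tuple[str, ...]:
        return self.base.node_labels

    def adjacency(self) -> np.ndarray:
        """Symmetric adjacency with zero diagonal; 1s if binarized else original r."""
        n = self.n_nodes
        a = np.zeros((n, n))
        for i, j in self.retained:
            v = 1.0 if self.binarized else self.base.weights[i, j]
            a[i, j] = a[j, i] = v
        return a

    def compatible_with(self, other: "SparsifiedMap") -> None:
        if self.node_labels != other.node_labels:
            raise ComparisonError("maps have different node labels / order")
        if self.sparsity != other.sparsity or self.binarized != other.binarized:
            raise ComparisonError("maps differ in sparsity level or weighting mode")


def sparsify(cmap: ConnectivityMap, sparsity: float, binarized: bool = False) -> SparsifiedMap:
    """Proportional threshold: keep the top positive edges at the given sparsity.

    The retained edge count is ``floor(sparsity * N(N-1)/2)`` (never exceeding
    the stated percentage), capped at the number of strictly positive
    off-diagonal edges. Ties at the threshold break lexicographically on
    (i, j) for cross-platform reproducibility.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ConfigurationError(f"sparsity must be in (0, 1], got {sparsity}")
    n = cmap.n_nodes
    k = int(np.floor(sparsity * n * (n - 1) / 2))
    iu, ju = np.triu_indices(n, k=1)
    w = cmap.weights[iu, ju]
    pos = w > 0
    candidates = sorted(
        zip(-w[pos], iu[pos], ju[pos])
    )  # descending weight, then lexicographic (i, j)
    if k > len(candidates):
        logger.warning(
            "requested %d edges at sparsity %.3g but only %d positive edges exist",
            k, sparsity, len(candidates),
        )
    retained = frozenset((int(i), int(j)) for _, i, j in candidates[:k])
    return SparsifiedMap(cmap, sparsity, binarized, retained)


def total_connectivity_strength(cmap: ConnectivityMap) -> float:
    """Sum of weights over all unordered node pairs, unfiltered (negatives included)."""
    iu, ju = np.triu_indices(cmap.n_nodes, k=1)
    return float(cmap.weights[iu, ju].sum())
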