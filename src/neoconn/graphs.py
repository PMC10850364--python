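"""Graph-theory characterization of sparsified connectivity maps.

Implements the four network measures used to contrast case and control
connectomes, applied literally to whatever adjacency (weighted r values or
binarized 0/1) the sparsified map supplies:

* clustering coefficient
      C_p = (1/N) sum_i [ sum_{j,k} a_ij a_ik a_jk / ((s_i - 1) s_i) ],
      s_i = sum_j a_ij;  nodes with s_i <= 1 (binarized: degree < 2)
      contribute 0, since the denominator degenerates.
* local network efficiency
      NE = (1/N) sum_i [ 1/(|G_i|(|G_i|-1)) sum_{j != k in G_i} 1/d_jk ],
      G_i = node i plus its direct neighbors, d_jk the shortest-path
      distance inside the subgraph induced by G_i (hop count for binarized
      maps, edge length 1/weight otherwise).
* modularity of a community partition
      M = sum_p [ e_pp - (sum_q e_pq)^2 ],
      e_pq the fraction of total edge weight between communities p and q
      (within-community weight fully on the diagonal); this is Newman's Q.
* normalized mutual information between two partitions, from the confusion
  matrix c_wv (nodes shared by community w of one partition and v of the
  other):
      MI = -2 sum c_wv ln(c_wv N / (c_w. c_.v))
           / [ sum_w c_w. ln(c_w./N) + sum_v c_.v ln(c_.v/N) ],
  which is 1 for identical partitions and 0 for independent ones.

Communities come from the seeded greedy Louvain modularity optimizer.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from .connectivity import SparsifiedMap
from .exceptions import ComparisonError, DimensionError, PartitionError

DEFAULT_METRIC_GRID: Tuple[float, ...] = (0.20, 0.25, 0.30, 0.35, 0.40, 0.45)


# ---------------------------------------------------------------- partitions
@dataclass
class CommunityPartition:
    """Node -> community assignment with labels contiguous from 1."""

    assignment: np.ndarray  # int labels, 1..n_communities
    node_labels: Tuple[str, ...]
    seed: Optional[int] = None

    def __post_init__(self):
        a = np.asarray(self.assignment, int)
        if a.ndim != 1 or a.shape[0] != len(self.node_labels):
            raise PartitionError("assignment must give one community per node")
        labels = np.unique(a)
        if not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise PartitionError("community labels must be contiguous from 1")
        self.assignment = a

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max())

    @property
    def n_nodes(self) -> int:
        return self.assignment.shape[0]


def _canonical_labels(groups: Sequence[set], n_nodes: int) -> np.ndarray:
    """Relabel communities 1..K in order of their smallest member node."""
    ordered = sorted(groups, key=min)
    out = np.empty(n_nodes, int)
    for lab, grp in enumerate(ordered, start=1):
        for node in grp:
            out[node] = lab
    return out


# ------------------------------------------------------------------ metrics
def _adjacency(sp: SparsifiedMap) -> np.ndarray:
    return sp.adjacency()


def clustering_coefficient(sp: SparsifiedMap) -> float:
    """Map-level clustering coefficient (weighted triangle density)."""
    a = _adjacency(sp)
    n = a.shape[0]
    if n < 3:
        raise DimensionError("clustering coefficient needs at least 3 nodes")
    num = np.diag(a @ a @ a)  # sum_{j,k} a_ij a_ik a_jk
    s = a.sum(axis=1)
    contrib = np.zeros(n)
    ok = s > 1.0
    contrib[ok] = num[ok] / ((s[ok] - 1.0) * s[ok])
    return float(contrib.mean())


def _pairwise_distances(a: np.ndarray, binarized: bool) -> np.ndarray:
    """Shortest-path distances; edge length is 1 (hops) or 1/weight.

    Floyd-Warshall in numpy: the pipeline's graphs have at most 20 nodes,
    where this beats sparse-graph machinery by a wide margin.
    """
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    edge = a > 0
    d[edge] = 1.0 if binarized else 1.0 / a[edge]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return d


def nodal_efficiency_terms(sp: SparsifiedMap) -> np.ndarray:
    """Per-node local-efficiency terms (the bracketed summand of NE)."""
    a = _adjacency(sp)
    n = a.shape[0]
    terms = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i] > 0)
        gi = np.concatenate(([i], nbrs[nbrs != i]))
        g = gi.size
        if g < 2:
            continue
        d = _pairwise_distances(a[np.ix_(gi, gi)], sp.binarized)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        np.fill_diagonal(inv, 0.0)
        terms[i] = inv.sum() / (g * (g - 1))
    return terms


def local_efficiency(sp: SparsifiedMap) -> float:
    """Map-level local network efficiency."""
    a = sp.adjacency()
    if a.shape[0] < 2:
        raise DimensionError("local efficiency needs at least 2 nodes")
    return float(nodal_efficiency_terms(sp).mean())


def louvain_partition(sp: SparsifiedMap, seed: int = 0) -> CommunityPartition:
    """Seeded greedy Louvain modularity optimization on the retained edges.

    With an empty edge set every node becomes its own community (warned).
    If the optimizer ends below the trivial one-community partition's
    modularity (0), the trivial partition is returned instead.
    """
    n = sp.n_nodes
    if not sp.retained:
        warnings.warn("empty edge set: every node is its own community")
        return CommunityPartition(np.arange(1, n + 1), sp.node_labels, seed)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    a = sp.adjacency()
    for i, j in sp.retained:
        g.add_edge(i, j, weight=a[i, j])
    groups = nx.community.louvain_communities(g, weight="weight", seed=seed)
    part = CommunityPartition(_canonical_labels(groups, n), sp.node_labels, seed)
    if modularity(sp, part) < 0.0:
        part = CommunityPartition(np.ones(n, int), sp.node_labels, seed)
    return part


def modularity(sp: SparsifiedMap, partition: CommunityPartition) -> float:
    """Partition quality M = sum_p [e_pp - (sum_q e_pq)^2] on the sparsified map."""
    if partition.n_nodes != sp.n_nodes:
        raise PartitionError("partition does not cover the map's node set")
    a = sp.adjacency()
    total = a.sum()  # 2 x total edge weight
    if total == 0:
        return 0.0
    labels = partition.assignment
    k = partition.n_communities
    # e[p, q]: fraction of edge weight between communities (ordered-pair sums)
    onehot = np.eye(k)[labels - 1]  # (n, k)
    block = onehot.T @ a @ onehot / total  # e_pp on diagonal, 2*e_pq split otherwise
    e_pp = np.diag(block)
    row = block.sum(axis=1)  # community p's share of endpoint weight
    return float(np.sum(e_pp - row**2))


# ----------------------------------------------------------- partition MI
@dataclass
class ConfusionCounts:
    """Community-overlap counts between two partitions of the same node set."""

    counts: np.ndarray  # (n_communities_1, n_communities_2)
    n_nodes: int


def confusion_counts(p1: CommunityPartition, p2: CommunityPartition) -> ConfusionCounts:
    if p1.n_nodes != p2.n_nodes or p1.node_labels != p2.node_labels:
        raise ComparisonError("partitions are over different node sets")
    c = np.zeros((p1.n_communities, p2.n_communities))
    for w, v in zip(p1.assignment, p2.assignment):
        c[w - 1, v - 1] += 1
    return ConfusionCounts(c, p1.n_nodes)


def partition_mutual_information(p1: CommunityPartition, p2: CommunityPartition) -> float:
    """Normalized mutual information between two partitions, in [0, 1]."""
    cc = confusion_counts(p1, p2)
    c = cc.counts
    n = cc.n_nodes
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    mask = c > 0  # 0 * ln 0 := 0
    num = -2.0 * np.sum(c[mask] * np.log((c * n / np.outer(row, col))[mask]))
    denom = np.sum(row * np.log(row / n)) + np.sum(col * np.log(col / n))
    if denom == 0.0:
        # both partitions trivial (single community): identical clusterings
        return 1.0
    return float(num / denom)


# ------------------------------------------------------------ nodal features
@dataclass
class NodalFeatureVector:
    """Per-node local metrics used as classifier features."""

    strength: np.ndarray
    degree_centrality: np.ndarray
    closeness_centrality: np.ndarray
    clustering: np.ndarray
    efficiency: np.ndarray
    node_labels: Tuple[str, ...]
    sparsity: float

    FAMILIES = (
        "connectivity",
        "degree_centrality",
        "closeness_centrality",
        "clustering_coefficient",
        "nodal_efficiency",
    )

    def family(self, name: str) -> np.ndarray:
        return {
            "connectivity": self.strength,
            "degree_centrality": self.degree_centrality,
            "closeness_centrality": self.closeness_centrality,
            "clustering_coefficient": self.clustering,
            "nodal_efficiency": self.efficiency,
        }[name]


def nodal_features(sp: SparsifiedMap, closeness: str = "standard") -> NodalFeatureVector:
    """Per-node strength, centralities, clustering and efficiency terms.

    Closeness is the normalized (N-1)/sum_j d_ij, set to 0 for nodes with
    unreachable partners; ``closeness="harmonic"`` uses the mean inverse
    distance instead, which stays finite on disconnected graphs.
    """
    a = sp.adjacency()
    n = a.shape[0]
    if n < 2:
        raise DimensionError("nodal features need at least 2 nodes")
    strength = a.sum(axis=1)
    degree = (a > 0).sum(axis=1)
    d = _pairwise_distances(a, sp.binarized)
    off = ~np.eye(n, dtype=bool)
    if closeness == "harmonic":
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        clo = inv[off].reshape(n, n - 1).sum(axis=1) / (n - 1)
    else:
        dsum = np.where(np.isfinite(d), d, np.inf)[off].reshape(n, n - 1).sum(axis=1)
        with np.errstate(divide="ignore"):
            clo = np.where(np.isfinite(dsum) & (dsum > 0), (n - 1) / dsum, 0.0)
    num = np.diag(a @ a @ a)
    s = strength
    clus = np.zeros(n)
    ok = s > 1.0
    clus[ok] = num[ok] / ((s[ok] - 1.0) * s[ok])
    eff = nodal_efficiency_terms(sp)
    return NodalFeatureVector(
        strength, degree / (n - 1), clo, clus, eff, sp.node_labels, sp.sparsity
    )


# ------------------------------------------------------------- metric table
@dataclass
class GraphMetricSet:
    clustering_coefficient: float
    network_efficiency: float
    modularity: float
    n_communities: int
    sparsity: float
    signal_type: str
    subject_id: str


def graph_metrics(sp: SparsifiedMap, seed: int = 0) -> GraphMetricSet:
    """All map-level metrics for one sparsified map (one Louvain run)."""
    part = louvain_partition(sp, seed=seed)
    return GraphMetricSet(
        clustering_coefficient=clustering_coefficient(sp),
        network_efficiency=local_efficiency(sp),
        modularity=modularity(sp, part),
        n_communities=part.n_communities,
        sparsity=sp.sparsity,
        signal_type=sp.base.signal_type,
        subject_id=sp.base.subject_id,
    )


def metric_profile(maps: Iterable[SparsifiedMap], seed: int = 0):
    """Tidy per-subject, per-signal, per-sparsity metric table (DataFrame)."""
    import pandas as pd

    rows = []
    for sp in maps:
        m = graph_metrics(sp, seed=seed)
        rows.append(
            {
                "subject_id": m.subject_id,
                "signal_type": m.signal_type,
                "sparsity": m.sparsity,
                "clustering_coefficient": m.clustering_coefficient,
                "network_efficiency": m.network_efficiency,
                "modularity": m.modularity,
                "n_communities": m.n_communities,
            }
        )
    return pd.DataFrame(rows)
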