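import numpy as np
import pytest

from _oracles import (
    clustering_brute,
    local_efficiency_brute,
    modularity_brute,
    nmi_brute,
)
from neoconn import (
    CommunityPartition,
    ConnectivityMap,
    clustering_coefficient,
    local_efficiency,
    louvain_partition,
    metric_profile,
    modularity,
    nodal_features,
    partition_mutual_information,
    sparsify,
)
from neoconn.exceptions import ComparisonError, DimensionError, PartitionError


def binary_graph(n, edges):
    """Binarized sparsified map with the given edge set."""
    w = np.eye(n)
    for i, j in edges:
        w[i, j] = w[j, i] = 0.8
    cmap = ConnectivityMap(w, tuple(f"n{i}" for i in range(n)))
    return sparsify(cmap, 1.0, binarized=True)


def weighted_graph(rng, n, p=0.5):
    """Random weighted sparsified map (positive weights in (0, 1))."""
    w = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w[i, j] = w[j, i] = rng.uniform(0.1, 0.99)
    cmap = ConnectivityMap(w, tuple(f"n{i}" for i in range(n)))
    return sparsify(cmap, 1.0, binarized=False)


K4 = [(i, j) for i in range(4) for j in range(i + 1, 4)]
TWO_K3 = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]


class TestClustering:
    def test_complete_graph_is_one(self):
        assert clustering_coefficient(binary_graph(4, K4)) == pytest.approx(1.0)

    def test_star_graph_has_no_triangles(self):
        star = binary_graph(5, [(0, i) for i in range(1, 5)])
        assert clustering_coefficient(star) == 0.0

    def test_cycle_has_no_triangles(self):
        cycle = binary_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])
        assert clustering_coefficient(cycle) == 0.0

    def test_matches_brute_force_on_random_weighted_graphs(self, rng):
        for _ in range(10):
            sp = weighted_graph(rng, 6)
            assert clustering_coefficient(sp) == pytest.approx(
                clustering_brute(sp.adjacency()), abs=1e-12
            )

    def test_too_small_graph_rejected(self):
        with pytest.raises(DimensionError):
            clustering_coefficient(binary_graph(2, [(0, 1)]))


class TestLocalEfficiency:
    def test_complete_graph_is_one(self):
        assert local_efficiency(binary_graph(4, K4)) == pytest.approx(1.0)

    def test_edgeless_graph_is_zero(self):
        assert local_efficiency(binary_graph(4, [])) == 0.0

    def test_matches_exhaustive_path_oracle(self, rng):
        for _ in range(8):
            sp = weighted_graph(rng, 6)
            assert local_efficiency(sp) == pytest.approx(
                local_efficiency_brute(sp.adjacency(), binarized=False), abs=1e-12
            )
        for _ in range(8):
            n = 6
            edges = [
                (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.4
            ]
            sp = binary_graph(n, edges)
            assert local_efficiency(sp) == pytest.approx(
                local_efficiency_brute(sp.adjacency(), binarized=True), abs=1e-12
            )


class TestLouvain:
    def test_separates_disconnected_cliques(self):
        part = louvain_partition(binary_graph(6, TWO_K3), seed=0)
        assert part.n_communities == 2
        a = part.assignment
        assert a[0] == a[1] == a[2]
        assert a[3] == a[4] == a[5]
        assert a[0] != a[3]

    def test_clique_partition_is_optimal_over_two_set_partitions(self):
        """Exhaustive check: no 2-set partition beats the planted cliques."""
        from itertools import product

        sp = binary_graph(6, TWO_K3)
        best = max(
            modularity(
                sp,
                CommunityPartition(
                    np.array([1] + [x + 1 for x in bits]), sp.node_labels
                ),
            )
            for bits in product((0, 1), repeat=5)
        )
        planted = CommunityPartition(np.array([1, 1, 1, 2, 2, 2]), sp.node_labels)
        assert modularity(sp, planted) == pytest.approx(best)

    def test_complete_graph_is_one_community(self):
        part = louvain_partition(binary_graph(5, [(i, j) for i in range(5) for j in range(i + 1, 5)]), seed=1)
        assert part.n_communities == 1

    def test_deterministic_given_seed(self, rng):
        sp = weighted_graph(rng, 12, p=0.3)
        a = louvain_partition(sp, seed=42).assignment
        for _ in range(3):
            np.testing.assert_array_equal(louvain_partition(sp, seed=42).assignment, a)

    def test_empty_graph_singleton_communities(self):
        with pytest.warns(UserWarning, match="empty edge set"):
            part = louvain_partition(binary_graph(4, []), seed=0)
        assert part.n_communities == 4

    def test_recovers_planted_blocks(self):
        """Two 8-node blocks (p_in=0.9, p_out=0.1): recovered M >= planted M."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 16
            w = np.eye(n)
            for i in range(n):
                for j in range(i + 1, n):
                    p = 0.9 if (i < 8) == (j < 8) else 0.1
                    if rng.random() < p:
                        w[i, j] = w[j, i] = 0.8
            sp = sparsify(
                ConnectivityMap(w, tuple(f"n{i}" for i in range(n))), 1.0, True
            )
            planted = CommunityPartition(
                np.array([1] * 8 + [2] * 8), sp.node_labels
            )
            found = louvain_partition(sp, seed=seed)
            if modularity(sp, found) >= modularity(sp, planted) - 1e-12:
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestModularity:
    def test_single_community_is_zero(self):
        sp = binary_graph(5, [(0, 1), (1, 2), (3, 4)])
        part = CommunityPartition(np.ones(5, int), sp.node_labels)
        assert modularity(sp, part) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        """e_pp = 1/2 each, no cross edges: M = 2 (0.5 - 0.25) = 0.5."""
        sp = binary_graph(6, TWO_K3)
        part = CommunityPartition(np.array([1, 1, 1, 2, 2, 2]), sp.node_labels)
        assert modularity(sp, part) == pytest.approx(0.5)

    def test_matches_edge_loop_oracle(self, rng):
        for _ in range(10):
            sp = weighted_graph(rng, 7)
            labels = rng.integers(1, 4, size=7)
            labels = (
                np.unique(labels, return_inverse=True)[1] + 1
            )  # contiguous from 1
            part = CommunityPartition(labels, sp.node_labels)
            assert modularity(sp, part) == pytest.approx(
                modularity_brute(sp.adjacency(), labels), abs=1e-12
            )

    def test_matches_networkx_newman_q(self, rng):
        """Cross-check against the independent networkx implementation."""
        import networkx as nx

        for _ in range(5):
            sp = weighted_graph(rng, 8)
            part = louvain_partition(sp, seed=0)
            g = nx.from_numpy_array(sp.adjacency())
            comms = [
                {i for i in range(8) if part.assignment[i] == c}
                for c in range(1, part.n_communities + 1)
            ]
            assert modularity(sp, part) == pytest.approx(
                nx.community.modularity(g, comms, weight="weight"), abs=1e-12
            )

    def test_uncovered_partition_rejected(self):
        sp = binary_graph(4, K4)
        with pytest.raises(PartitionError):
            modularity(sp, CommunityPartition(np.array([1, 1, 2]), sp.node_labels[:3]))


class TestMutualInformation:
    def _part(self, labels):
        labels = np.asarray(labels, int)
        return CommunityPartition(labels, tuple(f"n{i}" for i in range(len(labels))))

    def test_identical_two_by_two_partitions(self):
        """Sizes 2+2 over 4 nodes: numerator and denominator both -8 ln 2."""
        p = self._part([1, 1, 2, 2])
        assert partition_mutual_information(p, p) == pytest.approx(1.0)

    def test_any_partition_agrees_with_itself(self, rng):
        for _ in range(5):
            labels = np.unique(rng.integers(1, 5, size=12), return_inverse=True)[1] + 1
            p = self._part(labels)
            assert partition_mutual_information(p, p) == pytest.approx(1.0)

    def test_independent_partitions_score_low(self, rng):
        vals = []
        for _ in range(10):
            l1 = np.unique(rng.integers(1, 5, 200), return_inverse=True)[1] + 1
            l2 = np.unique(rng.integers(1, 5, 200), return_inverse=True)[1] + 1
            vals.append(
                partition_mutual_information(self._part(l1), self._part(l2))
            )
        assert np.mean(vals) < 0.1

    def test_symmetric_and_relabel_invariant(self, rng):
        l1 = np.unique(rng.integers(1, 4, 20), return_inverse=True)[1] + 1
        l2 = np.unique(rng.integers(1, 4, 20), return_inverse=True)[1] + 1
        p1, p2 = self._part(l1), self._part(l2)
        mi = partition_mutual_information(p1, p2)
        assert partition_mutual_information(p2, p1) == pytest.approx(mi, abs=1e-12)
        # relabel communities of p1 (swap 1 <-> max)
        swapped = l1.copy()
        mx = swapped.max()
        swapped[l1 == 1], swapped[l1 == mx] = mx, 1
        swapped = np.unique(swapped, return_inverse=True)[1] + 1
        assert partition_mutual_information(self._part(swapped), p2) == pytest.approx(
            mi, abs=1e-12
        )

    def test_matches_loop_oracle_and_sklearn(self, rng):
        from sklearn.metrics import normalized_mutual_info_score

        for _ in range(10):
            l1 = np.unique(rng.integers(1, 5, 30), return_inverse=True)[1] + 1
            l2 = np.unique(rng.integers(1, 5, 30), return_inverse=True)[1] + 1
            mi = partition_mutual_information(self._part(l1), self._part(l2))
            assert mi == pytest.approx(nmi_brute(list(l1), list(l2)), abs=1e-12)
            assert mi == pytest.approx(
                normalized_mutual_info_score(l1, l2, average_method="arithmetic"),
                abs=1e-9,
            )

    def test_mismatched_node_sets_rejected(self):
        p1 = self._part([1, 2, 1])
        p2 = CommunityPartition(np.array([1, 2]), ("a", "b"))
        with pytest.raises(ComparisonError):
            partition_mutual_information(p1, p2)


class TestNodalFeatures:
    def test_complete_graph_centralities(self):
        f = nodal_features(binary_graph(4, K4))
        np.testing.assert_allclose(f.degree_centrality, 1.0)
        np.testing.assert_allclose(f.closeness_centrality, 1.0)
        np.testing.assert_allclose(f.clustering, 1.0)
        np.testing.assert_allclose(f.efficiency, 1.0)
        np.testing.assert_allclose(f.strength, 3.0)

    def test_path_graph_closeness(self):
        f = nodal_features(binary_graph(3, [(0, 1), (1, 2)]))
        assert f.closeness_centrality[1] == pytest.approx(1.0)  # center: 2/2
        assert f.closeness_centrality[0] == pytest.approx(2.0 / 3.0)

    def test_matches_per_definition_oracles(self, rng):
        for _ in range(5):
            sp = weighted_graph(rng, 6)
            a = sp.adjacency()
            f = nodal_features(sp)
            n = 6
            np.testing.assert_allclose(f.strength, a.sum(axis=1), atol=1e-12)
            np.testing.assert_allclose(
                f.degree_centrality, (a > 0).sum(axis=1) / (n - 1), atol=1e-12
            )
            # nodal terms average to the map-level metrics
            assert f.clustering.mean() == pytest.approx(
                clustering_coefficient(sp), abs=1e-12
            )
            assert f.efficiency.mean() == pytest.approx(
                local_efficiency(sp), abs=1e-12
            )

    def test_harmonic_closeness_on_disconnected_graph(self):
        f_std = nodal_features(binary_graph(4, [(0, 1)]))
        f_har = nodal_features(binary_graph(4, [(0, 1)]), closeness="harmonic")
        assert f_std.closeness_centrality[0] == 0.0  # unreachable pairs
        assert f_har.closeness_centrality[0] == pytest.approx(1.0 / 3.0)


class TestMetricProfile:
    def test_single_map_row_matches_direct_calls(self, rng):
        sp = weighted_graph(rng, 8)
        sp.base.subject_id = "s1"
        sp.base.signal_type = "HbO"
        df = metric_profile([sp], seed=3)
        assert len(df) == 1
        row = df.iloc[0]
        assert row.clustering_coefficient == pytest.approx(clustering_coefficient(sp))
        assert row.network_efficiency == pytest.approx(local_efficiency(sp))
        part = louvain_partition(sp, seed=3)
        assert row.modularity == pytest.approx(modularity(sp, part))

    def test_row_count_is_grid_times_signals_times_subjects(self, rng):
        maps = []
        for sid in ("a", "b", "c"):
            for sig in ("HbO", "Hbr"):
                cmap = ConnectivityMap(
                    np.corrcoef(rng.standard_normal((8, 40))),
                    tuple(f"n{i}" for i in range(8)),
                    sig,
                    sid,
                )
                maps.extend(sparsify(cmap, s, True) for s in (0.2, 0.3))
        df = metric_profile(maps)
        assert len(df) == 2 * 2 * 3

    def test_denser_graphs_approach_complete_graph_clustering(self):
        """Adding edges drives C_p toward the complete-graph value 1."""
        n = 6
        all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        rng = np.random.default_rng(0)
        order = rng.permutation(len(all_edges))
        cps = []
        for k in (6, 9, 12, 15):
            edges = [all_edges[i] for i in order[:k]]
            cps.append(clustering_coefficient(binary_graph(n, edges)))
        assert cps[-1] == pytest.approx(1.0)
        assert cps == sorted(cps)
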