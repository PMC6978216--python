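"""Graph measures vs brute-force oracles; rich-club edge classification."""

import numpy as np
import pytest

from svdnet.connectome import ConnectivityMatrix, Parcellation
from svdnet.network_metrics import (
    class_mean_strength,
    classify_edges,
    degree_rank_report,
    global_efficiency,
    network_density,
    node_degree,
    total_network_strength,
)


def floyd_warshall_efficiency(weights: np.ndarray) -> float:
    """Independent oracle: explicit Floyd-Warshall on lengths 1/w."""
    n = weights.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                dist[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def complete_matrix(n, weight=1.0):
    parc = Parcellation(tuple(f"r{i}" for i in range(n)))
    w = np.full((n, n), float(weight))
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, parc)


class TestDegreeDensityStrength:
    def test_all_zero_matrix(self, abc_parcellation):
        m = ConnectivityMatrix(np.zeros((3, 3)), abc_parcellation)
        assert np.all(node_degree(m) == 0)
        assert network_density(m) == 0.0
        assert total_network_strength(m) == 0.0
        assert global_efficiency(m) == 0.0

    def test_complete_graph(self):
        m = complete_matrix(5)
        assert np.all(node_degree(m) == 4)
        assert network_density(m) == 1.0
        assert global_efficiency(m) == pytest.approx(1.0)

    def test_two_edges_degree_vector(self):
        parc = Parcellation(("a", "b", "c", "d"))
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        m = ConnectivityMatrix(w, parc)
        assert node_degree(m).tolist() == [2, 1, 1, 0]

    def test_density_90_nodes_400_edges(self):
        rng = np.random.default_rng(5)
        parc = Parcellation(tuple(f"r{i}" for i in range(90)))
        iu, ju = np.triu_indices(90, k=1)
        pick = rng.choice(iu.size, size=400, replace=False)
        w = np.zeros((90, 90))
        w[iu[pick], ju[pick]] = 1.0
        w += w.T
        m = ConnectivityMatrix(w, parc)
        assert network_density(m) == pytest.approx(400 / 4005)

    def test_strength_sums_each_edge_once(self, abc_parcellation):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.5
        w[1, 2] = w[2, 1] = 2.0
        m = ConnectivityMatrix(w, abc_parcellation)
        assert total_network_strength(m) == pytest.approx(4.5)

    def test_density_requires_two_nodes(self):
        m = ConnectivityMatrix(np.zeros((1, 1)), Parcellation(("solo",)))
        with pytest.raises(ValueError):
            network_density(m)


class TestGlobalEfficiency:
    def test_three_node_path(self, abc_parcellation):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        m = ConnectivityMatrix(w, abc_parcellation)
        # pairs: A-B d=1, B-C d=1, A-C d=2 -> (1 + 1 + 0.5)/3
        assert global_efficiency(m) == pytest.approx(5 / 6)

    def test_matches_floyd_warshall_oracle_on_random_graphs(self, matrix_factory):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = rng.integers(2, 13)
            m = matrix_factory(rng, int(n), density=rng.uniform(0.1, 0.9))
            assert global_efficiency(m) == pytest.approx(
                floyd_warshall_efficiency(m.weights), abs=1e-9
            )

    def test_monotone_under_edge_addition(self, matrix_factory):
        rng = np.random.default_rng(7)
        for _ in range(40):
            m = matrix_factory(rng, 9, density=0.3)
            iu, ju = np.triu_indices(9, k=1)
            absent = [(i, j) for i, j in zip(iu, ju) if m.weights[i, j] == 0]
            if not absent:
                continue
            i, j = absent[rng.integers(len(absent))]
            w2 = m.weights.copy()
            w2[i, j] = w2[j, i] = rng.uniform(0.2, 5.0)
            m2 = ConnectivityMatrix(w2, m.parcellation)
            assert global_efficiency(m2) >= global_efficiency(m) - 1e-12
            assert network_density(m2) > network_density(m)
            assert total_network_strength(m2) > total_network_strength(m)

    def test_scaling_weights_scales_efficiency_and_strength(self, matrix_factory):
        rng = np.random.default_rng(11)
        m = matrix_factory(rng, 10, density=0.5)
        c = 3.7
        m2 = ConnectivityMatrix(m.weights * c, m.parcellation)
        assert global_efficiency(m2) == pytest.approx(c * global_efficiency(m))
        assert total_network_strength(m2) == pytest.approx(
            c * total_network_strength(m)
        )

    def test_binary_option_ignores_weights(self, matrix_factory):
        rng = np.random.default_rng(13)
        m = matrix_factory(rng, 8, density=0.5)
        binarized = ConnectivityMatrix(
            (m.weights > 0).astype(float), m.parcellation
        )
        assert global_efficiency(m, binary=True) == pytest.approx(
            global_efficiency(binarized)
        )


class TestEdgeClassification:
    def test_three_classes_counted(self, small_rich_parcellation):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (2, 3)]:  # rich-rich, rich-peri, peri-peri
            w[i, j] = w[j, i] = 1.0
        m = ConnectivityMatrix(w, small_rich_parcellation)
        part = classify_edges(m)
        assert part.class_counts == {"rich_club": 1, "feeder": 1, "peripheral": 1}

    def test_all_rich_set_makes_all_edges_rich(self, matrix_factory):
        rng = np.random.default_rng(3)
        m = matrix_factory(rng, 6, density=0.6, rich_labels=range(6))
        part = classify_edges(m)
        assert part.class_counts["rich_club"] == m.edge_count()

    def test_empty_rich_set_warns_and_all_peripheral(self, matrix_factory):
        rng = np.random.default_rng(4)
        m = matrix_factory(rng, 6, density=0.6)
        with pytest.warns(UserWarning, match="rich-club set is empty"):
            part = classify_edges(m)
        assert part.class_counts["peripheral"] == m.edge_count()

    def test_partition_complete_on_random_instances(self, matrix_factory):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            k = int(rng.integers(0, n))
            m = matrix_factory(rng, n, density=rng.uniform(0.2, 0.9),
                               rich_labels=rng.choice(n, size=k, replace=False))
            if k == 0:
                with pytest.warns(UserWarning):
                    part = classify_edges(m)
            else:
                part = classify_edges(m)
            assert sum(part.class_counts.values()) == m.edge_count()

    def test_class_mean_strength(self, small_rich_parcellation):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 2.0   # rich
        w[0, 2] = w[2, 0] = 4.0   # feeder
        m = ConnectivityMatrix(w, small_rich_parcellation)
        part = classify_edges(m)
        rich, feeder, peripheral = class_mean_strength(part, m)
        assert rich == pytest.approx(2.0)
        assert feeder == pytest.approx(4.0)
        assert np.isnan(peripheral)  # empty class is missing, not zero

    def test_uniform_weight_means_equal_weight(self, matrix_factory):
        rng = np.random.default_rng(21)
        m = matrix_factory(rng, 8, density=0.9, rich_labels=(0, 1, 2))
        u = ConnectivityMatrix((m.weights > 0) * 2.5, m.parcellation)
        part = classify_edges(u)
        for v in class_mean_strength(part, u):
            if not np.isnan(v):
                assert v == pytest.approx(2.5)


class TestDegreeRankReport:
    def test_star_center_is_rank_one(self):
        parc = Parcellation(("hub", "a", "b", "c"), rich_club_labels=("hub",))
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        rep = degree_rank_report(ConnectivityMatrix(w, parc), k=1)
        assert rep.ranks.tolist() == [1]
        assert rep.all_within_top_k

    def test_all_equal_degrees_all_rank_one(self):
        m = complete_matrix(5)
        parc = Parcellation(m.parcellation.labels, rich_club_labels=("r0", "r3"))
        m2 = ConnectivityMatrix(m.weights, parc)
        rep = degree_rank_report(m2, k=1)
        assert rep.ranks.tolist() == [1, 1]
        assert rep.all_within_top_k

    def test_flags_match_exhaustive_sort_oracle(self, matrix_factory):
        rng = np.random.default_rng(17)
        for _ in range(50):
            m = matrix_factory(rng, 10, density=rng.uniform(0.2, 0.8),
                               rich_labels=(0, 4, 7))
            k = int(rng.integers(1, 10))
            rep = degree_rank_report(m, k=k)
            deg = (m.weights > 0).sum(axis=1)
            for label, d, flag in zip(rep.labels, rep.degrees, rep.within_top_k):
                # within top-k iff fewer than k nodes strictly above
                assert flag == (np.sum(deg > d) < k)
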