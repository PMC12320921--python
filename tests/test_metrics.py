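import numpy as np
import pytest

from devconn.io import ConnectomeMatrix
from devconn.metrics import (
    local_clustering_positive,
    local_clustering_signed,
    modularity_signed,
    partition_quality,
    weighted_degree,
)
from oracles import (
    asymmetric_signed_modularity,
    brute_clustering_positive,
    brute_clustering_signed,
    exhaustive_best_modularity,
    random_signed_graph,
)


class TestModularity:
    def test_two_disconnected_triangles(self, two_triangle_graph):
        res = modularity_signed(two_triangle_graph, n_restarts=10, seed=1)
        assert res.Q == pytest.approx(0.5, abs=1e-12)
        mem = res.membership([f"ROI{i + 1:03d}" for i in range(6)])
        assert mem[0] == mem[1] == mem[2]
        assert mem[3] == mem[4] == mem[5]
        assert mem[0] != mem[3]
        assert sorted(set(res.partition.values())) == [1, 2]

    def test_trivial_partition_scores_zero(self):
        w = np.ones((4, 4)) - np.eye(4)
        q = partition_quality(w, np.zeros(4, dtype=int))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_signed_four_node_matches_exhaustive(self):
        w = np.array(
            [
                [0.0, 0.8, -0.2, -0.2],
                [0.8, 0.0, -0.2, -0.2],
                [-0.2, -0.2, 0.0, 0.8],
                [-0.2, -0.2, 0.8, 0.0],
            ]
        )
        res = modularity_signed(w, n_restarts=20, seed=3)
        best_q, best_p = exhaustive_best_modularity(w)
        assert res.Q == pytest.approx(best_q, abs=1e-9)
        labels = [f"ROI{i + 1:03d}" for i in range(4)]
        mem = res.membership(labels)
        assert mem[0] == mem[1] and mem[2] == mem[3] and mem[0] != mem[2]

    def test_never_beats_exhaustive_on_small_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 7))
            w = random_signed_graph(rng, n, density=0.6)
            if np.all(w == 0):
                continue
            res = modularity_signed(w, n_restarts=20, seed=7)
            best_q, _ = exhaustive_best_modularity(w)
            assert res.Q <= best_q + 1e-9
            # the returned Q must equal the Q of the returned partition
            labels = [f"ROI{i + 1:03d}" for i in range(n)]
            assert partition_quality(w, res.membership(labels)) == pytest.approx(
                res.Q, abs=1e-9
            )

    def test_quality_matches_definition_oracle(self, rng):
        w = random_signed_graph(rng, 6, density=0.7)
        mem = np.array([0, 0, 1, 1, 2, 2])
        assert partition_quality(w, mem) == pytest.approx(
            asymmetric_signed_modularity(w, mem), abs=1e-12
        )

    def test_deterministic_given_seed(self, two_triangle_graph):
        a = modularity_signed(two_triangle_graph, n_restarts=5, seed=11)
        b = modularity_signed(two_triangle_graph, n_restarts=5, seed=11)
        assert a.Q == b.Q and a.partition == b.partition

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            modularity_signed(np.array([[0.0, 1.0], [0.5, 0.0]]), seed=0)


class TestClusteringPositive:
    def test_uniform_triangle_is_fully_clustered(self):
        w = (np.ones((3, 3)) - np.eye(3)) * 0.7
        assert np.allclose(local_clustering_positive(w), 1.0)

    def test_path_has_no_triangles(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert np.allclose(local_clustering_positive(w), 0.0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 15))
            w = np.abs(random_signed_graph(rng, n, density=0.5))
            assert np.allclose(
                local_clustering_positive(w), brute_clustering_positive(w), atol=1e-12
            )

    def test_negative_weights_rejected(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="signed"):
            local_clustering_positive(w)


class TestClusteringSigned:
    def test_positive_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert np.allclose(local_clustering_signed(w), 1.0)

    def test_frustrated_triangle_is_anticlustered(self):
        w = np.array([[0, 1, 1], [1, 0, -1], [1, -1, 0]], dtype=float)
        assert np.allclose(local_clustering_signed(w), -1.0)

    def test_isolated_node_defaults_to_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        c = local_clustering_signed(w)
        assert c[2] == 0.0

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 15))
            w = random_signed_graph(rng, n, density=0.5)
            assert np.allclose(
                local_clustering_signed(w), brute_clustering_signed(w), atol=1e-12
            )

    def test_agrees_with_positive_variant_on_binary_graphs(self, rng):
        w = (np.abs(random_signed_graph(rng, 10, density=0.5)) > 0).astype(float)
        assert np.allclose(
            local_clustering_signed(w), local_clustering_positive(w), atol=1e-12
        )


class TestWeightedDegree:
    def test_worked_example(self):
        w = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        assert np.allclose(weighted_degree(w), [1.0, 0.5, 0.5])

    def test_zero_matrix(self):
        assert np.allclose(weighted_degree(np.zeros((4, 4))), 0.0)

    def test_complete_graph_constant(self):
        c = 0.37
        w = c * (np.ones((5, 5)) - np.eye(5))
        assert np.allclose(weighted_degree(w), c)

    def test_linearity(self, rng):
        a = np.abs(random_signed_graph(rng, 8, density=0.6))
        b = np.abs(random_signed_graph(rng, 8, density=0.6))
        assert np.allclose(
            weighted_degree(2 * a + 3 * b),
            2 * weighted_degree(a) + 3 * weighted_degree(b),
        )

    def test_single_region_rejected(self):
        m = ConnectomeMatrix(np.zeros((1, 1)), ["a"], "SC")
        with pytest.raises(ValueError, match="2 regions"):
            weighted_degree(m)
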