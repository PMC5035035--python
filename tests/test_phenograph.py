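import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from cytopipe import synthetic
from cytopipe.phenograph import build_knn, jaccard_weights, louvain_partition, phenograph


class TestKnn:
    def test_three_points_on_a_line(self):
        data = np.array([[0.0], [1.0], [3.0]])
        nn = build_knn(data, k=1)
        np.testing.assert_array_equal(nn.ravel(), [1, 0, 1])

    def test_full_neighborhood_at_k_n_minus_one(self, rng):
        data = rng.normal(size=(8, 3))
        nn = build_knn(data, k=7)
        for i in range(8):
            assert set(nn[i]) == set(range(8)) - {i}

    def test_matches_sklearn_on_random_data(self, rng):
        data = rng.normal(size=(200, 10))
        nn = build_knn(data, k=15)
        ref = NearestNeighbors(n_neighbors=16).fit(data)
        _, ref_idx = ref.kneighbors(data)  # first neighbor is the point itself
        np.testing.assert_array_equal(np.sort(nn, axis=1), np.sort(ref_idx[:, 1:], axis=1))

    def test_chunked_equals_unchunked(self, rng):
        data = rng.normal(size=(150, 4))
        np.testing.assert_array_equal(
            build_knn(data, k=10, chunk_size=11), build_knn(data, k=10, chunk_size=150)
        )

    def test_rejects_bad_k(self, rng):
        with pytest.raises(ValueError):
            build_knn(rng.normal(size=(5, 2)), k=5)


class TestJaccard:
    def test_set_arithmetic(self):
        # NN(0) = {1,2,3}, NN(4) = {0,2,3} -> |{2,3}| / |{0,1,2,3}| = 0.5
        sets = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2], [0, 2, 3], [2, 3, 4]])
        w = jaccard_weights(sets)
        assert w[(0, 4)] == pytest.approx(0.5)

    def test_disjoint_sets_dropped(self):
        # 1 is a neighbor of 0 but the sets {1,2} and {3,4} share nothing
        sets = np.array([[1, 2], [3, 4], [3, 4], [2, 4], [2, 3]])
        w = jaccard_weights(sets)
        assert (0, 1) not in w

    def test_weights_bounded_and_symmetric_keys(self, rng):
        data = rng.normal(size=(60, 4))
        w = jaccard_weights(build_knn(data, k=8))
        assert all(0 < v <= 1 for v in w.values())
        assert all(i < j for i, j in w)


class TestLouvain:
    @staticmethod
    def _two_cliques():
        edges = {}
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    edges[(base + i, base + j)] = 1.0
        edges[(4, 5)] = 1.0
        return edges

    def test_two_cliques_split_at_bridge(self):
        result, modularity = louvain_partition(self._two_cliques(), n_cells=10, seed=0)
        assert result.n_clusters == 2
        assert len(set(result.labels[:5])) == 1 and len(set(result.labels[5:])) == 1
        # exhaustive oracle over all 2-block splits plus known optima families
        assert modularity == pytest.approx(self._oracle_modularity(), abs=1e-12)

    @staticmethod
    def _oracle_modularity():
        """Best modularity over every partition of the 10-node graph."""
        import networkx as nx

        edges = TestLouvain._two_cliques()
        g = nx.Graph()
        g.add_nodes_from(range(10))
        g.add_weighted_edges_from([(i, j, w) for (i, j), w in edges.items()])

        def partitions(items):
            if not items:
                yield []
                return
            head, rest = items[0], items[1:]
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [part[i] + [head]] + part[i + 1 :]
                yield part + [[head]]

        best = -1.0
        for part in partitions(list(range(10))):
            q = nx.community.modularity(g, [set(p) for p in part], weight="weight")
            best = max(best, q)
        return best

    def test_single_clique_is_one_community(self):
        edges = {(i, j): 1.0 for i in range(6) for j in range(i + 1, 6)}
        result, _ = louvain_partition(edges, n_cells=6, seed=0)
        assert result.n_clusters == 1

    def test_isolated_cells_become_singletons(self):
        edges = {(0, 1): 1.0, (1, 2): 1.0}
        result, _ = louvain_partition(edges, n_cells=5, seed=0)
        assert result.labels[3] != result.labels[4]
        assert np.all(result.labels >= 1)

    def test_beats_singleton_partition(self, rng):
        data = rng.normal(size=(80, 5))
        w = jaccard_weights(build_knn(data, k=10))
        _, modularity = louvain_partition(w, n_cells=80, seed=0)
        assert modularity >= 0.0  # all-singletons modularity is <= 0

    def test_planted_partition_recovery(self):
        rng = np.random.default_rng(7)
        truth = np.repeat(np.arange(4), 100)
        edges = {}
        for i in range(400):
            for j in range(i + 1, 400):
                p = 0.5 if truth[i] == truth[j] else 0.05
                if rng.random() < p:
                    edges[(i, j)] = 1.0
        result, _ = louvain_partition(edges, n_cells=400, seed=0)
        assert adjusted_rand_score(truth, result.labels) >= 0.9


class TestPhenograph:
    def test_four_blobs_recovered(self):
        data, truth = synthetic.marker_mixture(4, 250, 10, 8.0, seed=3)
        result = phenograph(data, k=30, seed=3)
        assert result.n_clusters == 4
        assert adjusted_rand_score(truth, result.labels) >= 0.99

    def test_seeded_determinism(self, rng):
        data = rng.normal(size=(200, 6))
        a = phenograph(data, k=15, seed=1)
        b = phenograph(data, k=15, seed=1)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_two_tiny_blobs(self):
        data = np.vstack([np.zeros((5, 2)), np.full((5, 2), 50.0)])
        data += np.random.default_rng(0).normal(0, 0.1, data.shape)
        result = phenograph(data, k=4, seed=0)
        assert result.n_clusters == 2

    def test_rejects_k_not_below_n(self, rng):
        with pytest.raises(ValueError):
            phenograph(rng.normal(size=(10, 3)), k=10)
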