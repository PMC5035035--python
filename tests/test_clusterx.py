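import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cytopipe import synthetic
from cytopipe.clusterx import (
    ClusterXParams,
    DensityPeakStats,
    assign_labels,
    clusterx,
    compute_sigma,
    detect_peaks_esd,
    generalized_esd,
    local_density,
    nearest_higher_density,
    pairwise_distance_quantile,
)
from cytopipe.metrics import cluster_f_measure


def full_matrix_oracle(data, dc):
    """Reference rho/delta/nhd from one explicit n x n distance matrix."""
    d = cdist(data, data)
    rho = np.exp(-((d / dc) ** 2)).sum(axis=1) - 1.0
    n = len(rho)
    idx = np.arange(n)
    delta = np.empty(n)
    nhd = np.empty(n, dtype=np.int64)
    for i in range(n):
        higher = (rho > rho[i]) | ((rho == rho[i]) & (idx < i))
        if higher.any():
            masked = np.where(higher, d[i], np.inf)
            delta[i] = masked.min()
            nhd[i] = masked.argmin()
        else:
            delta[i] = d[i].max()
            nhd[i] = i
    return rho, delta, nhd


class TestDensity:
    def test_two_points_at_dc(self):
        data = np.array([[0.0, 0.0], [1.0, 0.0]])
        rho = local_density(data, dc=1.0)
        np.testing.assert_allclose(rho, np.exp(-1.0), rtol=1e-12)

    def test_remote_point_has_negligible_density(self, rng):
        cloud = rng.normal(0, 0.01, size=(50, 2))
        data = np.vstack([cloud, [[100.0, 0.0]]])
        rho = local_density(data, dc=1.0)
        assert rho[-1] < 1e-300 + 50 * np.exp(-1e4) + 1e-12

    @pytest.mark.parametrize("chunk", [7, 100, 500])
    def test_chunking_is_invisible(self, rng, chunk):
        data = rng.normal(size=(500, 2))
        dc = pairwise_distance_quantile(data, 0.02, chunk_size=chunk)
        assert dc == pytest.approx(pairwise_distance_quantile(data, 0.02, chunk_size=500))
        rho_ref, delta_ref, nhd_ref = full_matrix_oracle(data, dc)
        rho = local_density(data, dc, chunk_size=chunk)
        delta, nhd = nearest_higher_density(data, rho, chunk_size=chunk)
        np.testing.assert_array_equal(rho, rho_ref)
        np.testing.assert_array_equal(delta, delta_ref)
        np.testing.assert_array_equal(nhd, nhd_ref)

    def test_collinear_hand_example(self):
        data = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        rho = np.array([3.0, 2.0, 1.0])
        delta, nhd = nearest_higher_density(data, rho)
        np.testing.assert_array_equal(delta, [3.0, 1.0, 2.0])
        np.testing.assert_array_equal(nhd, [0, 0, 1])

    def test_identical_points_tie_break(self):
        data = np.zeros((5, 2))
        rho = local_density(data, dc=1.0)
        delta, nhd = nearest_higher_density(data, rho)
        # index 0 wins the density-rank tie; everyone else sits at distance 0
        assert nhd[0] == 0
        np.testing.assert_array_equal(delta, np.zeros(5))

    def test_rejects_bad_dc(self):
        with pytest.raises(ValueError):
            local_density(np.zeros((3, 2)), dc=0.0)


class TestEsd:
    def test_detects_exactly_the_spiked_outliers(self):
        rng = np.random.default_rng(42)
        background = rng.normal(0.1, 0.01, size=200)
        spikes = np.array([0.9, 0.92, 0.95, 0.97, 1.0])
        x = np.concatenate([background, spikes])
        found = generalized_esd(x, alpha=0.001, max_outliers=50)
        assert sorted(found) == [200, 201, 202, 203, 204]

    def test_pure_normal_rarely_flags(self):
        hits = 0
        for seed in range(200):
            x = np.random.default_rng(seed).normal(size=1000)
            if generalized_esd(x, alpha=0.001, max_outliers=20):
                hits += 1
        assert hits / 200 <= 0.05

    def test_count_nondecreasing_in_alpha(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(size=300), [5.0, 5.5, 6.0]])
        counts = [
            len(generalized_esd(x, alpha=a, max_outliers=30))
            for a in (0.001, 0.005, 0.01, 0.05)
        ]
        assert counts == sorted(counts)

    def test_degenerate_sigma_returns_density_argmax(self):
        stats = DensityPeakStats(
            rho=np.array([1.0, 5.0, 2.0, 1.0]),
            delta=np.ones(4),
            nhd=np.array([1, 1, 1, 0]),
            sigma=np.full(4, 0.3),
        )
        assert detect_peaks_esd(stats) == [1]


class TestAssignment:
    def _stats(self, rho, nhd):
        n = len(rho)
        return DensityPeakStats(
            rho=np.asarray(rho, float),
            delta=np.ones(n),
            nhd=np.asarray(nhd),
            sigma=np.ones(n),
        )

    def test_chain_propagates_to_single_peak(self):
        # c(idx 2, densest, peak) <- b(idx 1) <- a(idx 0)
        stats = self._stats([1.0, 2.0, 3.0], [1, 2, 2])
        result = assign_labels(stats, peaks=[2])
        np.testing.assert_array_equal(result.labels, [1, 1, 1])

    def test_singleton_peaks_get_density_ordered_labels(self):
        stats = self._stats([5.0, 9.0, 7.0], [1, 1, 1])
        result = assign_labels(stats, peaks=[0, 1, 2])
        np.testing.assert_array_equal(result.labels, [3, 1, 2])
        assert result.centers == [1, 2, 0]

    def test_everything_labeled(self, rng):
        data = rng.normal(size=(200, 2))
        result = clusterx(data)
        assert np.all(result.labels >= 1)

    def test_requires_at_least_one_peak(self):
        with pytest.raises(ValueError):
            assign_labels(self._stats([1.0, 2.0], [1, 1]), peaks=[])


class TestClusterX:
    def test_recovers_r15_layout_across_alpha(self):
        data, labels = synthetic.r15_like(seed=0)
        for alpha in (0.001, 0.005, 0.01, 0.05):
            result = clusterx(data, ClusterXParams(alpha=alpha))
            assert result.n_clusters == 15
        result = clusterx(data)
        assert cluster_f_measure(labels, result.labels) >= 0.99

    def test_two_blobs_perfect_f_measure(self, blob_pair):
        data, labels = blob_pair
        result = clusterx(data)
        assert result.n_clusters == 2
        assert cluster_f_measure(labels, result.labels) == 1.0

    def test_deterministic(self, blob_pair):
        data, _ = blob_pair
        a = clusterx(data)
        b = clusterx(data)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_rejects_tiny_input(self, rng):
        with pytest.raises(ValueError, match="too few"):
            clusterx(rng.normal(size=(5, 2)))

    def test_sigma_scores_peaks_highest(self):
        data, labels = synthetic.r15_like(seed=1)
        dc = pairwise_distance_quantile(data, 0.02)
        rho = local_density(data, dc)
        delta, _ = nearest_higher_density(data, rho)
        sigma = compute_sigma(rho, delta)
        # the 15 largest sigma values are each in a distinct true cluster
        top = np.argsort(sigma)[::-1][:15]
        assert len(set(labels[top])) == 15
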