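import numpy as np
import pytest

from cytopipe import synthetic
from cytopipe.preprocess import ExpressionMatrix
from cytopipe.fcs import make_cell_ids
from cytopipe.progression import (
    cluster_medians,
    downsample_equal,
    fit_tobit,
    marker_trend,
    tobit_loglik,
)


class TestDownsample:
    labels = np.concatenate([np.ones(1000), np.full(300, 2)]).astype(int)

    def test_ceil_semantics(self):
        idx = downsample_equal(self.labels, target=500, seed=0)
        assert idx.size == 800
        assert (self.labels[idx] == 1).sum() == 500
        assert (self.labels[idx] == 2).sum() == 300
        assert np.unique(idx).size == idx.size  # without replacement

    def test_large_target_keeps_everything(self):
        idx = downsample_equal(self.labels, target=5000, seed=0)
        assert idx.size == 1300

    def test_seeded_reproducibility(self):
        a = downsample_equal(self.labels, target=100, seed=7)
        b = downsample_equal(self.labels, target=100, seed=7)
        np.testing.assert_array_equal(a, b)


class TestMedians:
    def test_componentwise_median(self):
        coords = np.array([[0.0, 0.0], [0.0, 2.0], [10.0, 4.0]])
        med = cluster_medians(coords, np.array([1, 1, 1]))
        np.testing.assert_array_equal(med.loc[1].to_numpy(), [0.0, 2.0])

    def test_singleton_cluster(self):
        coords = np.array([[1.0, 2.0], [5.0, 5.0]])
        med = cluster_medians(coords, np.array([1, 2]))
        np.testing.assert_array_equal(med.loc[2].to_numpy(), [5.0, 5.0])

    def test_permutation_invariance(self, rng):
        coords = rng.normal(size=(50, 3))
        labels = rng.integers(1, 4, size=50)
        perm = rng.permutation(50)
        a = cluster_medians(coords, labels)
        b = cluster_medians(coords[perm], labels[perm])
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


class TestTobit:
    def test_censoring_free_fit_reduces_to_ols(self, rng):
        x = rng.uniform(0, 10, 200)
        y = 1.0 + 2.0 * x  # noiseless, nothing at the limit
        fit = fit_tobit(x, y, left_limit=-1.0)
        assert fit.beta0 == pytest.approx(1.0, abs=1e-4)
        assert fit.beta1 == pytest.approx(2.0, abs=1e-4)
        assert fit.n_censored == 0

    def test_noisy_uncensored_matches_ols(self, rng):
        x, y, _ = synthetic.censored_linear(500, 1.0, 2.0, 0.5, -np.inf, seed=3)
        fit = fit_tobit(x, y, left_limit=-np.inf)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.beta1 == pytest.approx(slope, abs=1e-4)
        assert fit.beta0 == pytest.approx(intercept, abs=1e-4)

    def test_censored_recovery(self):
        estimates = [
            fit_tobit(*synthetic.censored_linear(2000, 0.5, 1.5, 1.0, 5.0, seed=s)[:2], 5.0).beta1
            for s in range(10)
        ]
        assert all(1.4 <= b <= 1.6 for b in estimates)

    def test_mle_improves_on_ols_start(self):
        x, y, _ = synthetic.censored_linear(500, 0.5, 1.5, 1.0, 5.0, seed=1)
        fit = fit_tobit(x, y, 5.0)
        b1, b0 = np.polyfit(x, y, 1)
        sigma0 = max(np.std(y - b0 - b1 * x), 1e-6)
        start_ll = tobit_loglik(np.array([b0, b1, np.log(sigma0)]), x, y, 5.0)
        assert fit.loglik >= start_ll

    def test_fully_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            fit_tobit(np.arange(20.0), np.zeros(20), left_limit=0.0)


class TestMarkerTrend:
    @staticmethod
    def _expression(rng, n=600, n_clusters=5):
        labels = np.repeat(np.arange(1, n_clusters + 1), n // n_clusters)
        component = labels + rng.normal(0, 0.2, n)  # ordered along dim 2
        coords = np.column_stack([rng.normal(size=n), component])
        truth_slope = 0.8
        marker = np.maximum(0.0, truth_slope * component + rng.normal(0, 0.3, n))
        expr = ExpressionMatrix(
            values=np.column_stack([marker, np.full(n, 2.0)]),
            cell_ids=make_cell_ids("x.fcs", n),
            marker_names=["Perforin", "flat"],
        )
        return expr, coords, labels, truth_slope

    def test_recovers_increasing_trend(self, rng):
        expr, coords, labels, truth = self._expression(rng)
        fit, curve = marker_trend(expr, coords, labels, [1, 2, 3, 4, 5], "Perforin")
        assert fit.beta1 > 0
        assert fit.beta1 == pytest.approx(truth, rel=0.10)
        assert curve.shape[0] == 100

    def test_reversing_component_negates_slope(self, rng):
        expr, coords, labels, _ = self._expression(rng)
        fwd, _ = marker_trend(expr, coords, labels, [1, 2, 3], "Perforin")
        rev, _ = marker_trend(expr, coords, labels, [1, 2, 3], "Perforin", reverse=True)
        assert rev.beta1 == pytest.approx(-fwd.beta1, abs=1e-5)

    def test_constant_marker_has_flat_trend(self, rng):
        expr, coords, labels, _ = self._expression(rng)
        fit, _ = marker_trend(expr, coords, labels, [1, 2, 3, 4, 5], "flat")
        assert fit.beta1 == pytest.approx(0.0, abs=1e-3)

    def test_missing_marker_raises(self, rng):
        expr, coords, labels, _ = self._expression(rng)
        with pytest.raises(KeyError, match="CD99"):
            marker_trend(expr, coords, labels, [1, 2], "CD99")
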