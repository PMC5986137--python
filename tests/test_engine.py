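import numpy as np
import pytest

from lasec import (
    LandmarkConfigurationSet,
    LandmarkSamplingCurve,
    SamplingSpec,
    gpa,
    informed_subsample_fit,
    landmarks_at_threshold,
    lasec,
    ordination_procrustes_fit,
    sim_coord,
    size_fit,
)
from lasec.containers import SamplingCurves
from lasec.exceptions import LandmarkDataError


@pytest.fixture(scope="module")
def curves():
    data = sim_coord(n_specimens=10, n_landmarks=8, n_dims=2,
                     covariance=0.1, seed=42)
    return lasec(data, SamplingSpec(n_iterations=30, seed=7))


class TestSamplingCurves:
    def test_landmark_counts_run_from_three_to_p(self, curves):
        assert curves.landmark_counts[0] == 3
        assert curves.landmark_counts[-1] == 8
        assert curves.shape_fits.shape == (30, 6)
        assert curves.size_fits.shape == (30, 6)

    def test_all_fits_in_unit_interval(self, curves):
        for fits in (curves.shape_fits, curves.size_fits):
            assert fits.min() >= -1e-12
            assert fits.max() <= 1.0 + 1e-12

    def test_full_subsample_has_perfect_fit(self, curves):
        assert np.all(curves.shape_fits[:, -1] == 1.0)
        assert np.all(curves.size_fits[:, -1] == 1.0)

    def test_medians_are_columnwise(self, curves):
        np.testing.assert_array_equal(curves.shape_median,
                                      np.median(curves.shape_fits, axis=0))
        np.testing.assert_array_equal(curves.size_median,
                                      np.median(curves.size_fits, axis=0))

    def test_orders_are_permutations(self, curves):
        expected = np.arange(8)
        for row in curves.landmark_orders:
            np.testing.assert_array_equal(np.sort(row), expected)

    def test_seed_reproducibility_bit_identical(self):
        data = sim_coord(n_specimens=8, n_landmarks=6, n_dims=2,
                         covariance=0.1, seed=3)
        a = lasec(data, SamplingSpec(n_iterations=10, seed=99))
        b = lasec(data, SamplingSpec(n_iterations=10, seed=99))
        assert np.array_equal(a.shape_fits, b.shape_fits)
        assert np.array_equal(a.size_fits, b.size_fits)
        assert np.array_equal(a.landmark_orders, b.landmark_orders)

    def test_stored_orders_reproduce_fits(self, curves):
        """Every recorded fit is recomputable from the stored permutation."""
        data = sim_coord(n_specimens=10, n_landmarks=8, n_dims=2,
                         covariance=0.1, seed=42)
        parent = gpa(data)
        it = 4
        perm = curves.landmark_orders[it]
        for j, k in enumerate(curves.landmark_counts[:-1]):
            sub = gpa(data.coords[:, perm[:k], :])
            shape = ordination_procrustes_fit(parent.shape_vars,
                                              sub.shape_vars).fit
            size = size_fit(parent.centroid_sizes, sub.centroid_sizes).fit
            assert shape == curves.shape_fits[it, j]
            assert size == curves.size_fits[it, j]

    def test_median_curve_trend_non_decreasing_smoothed(self):
        """The median fit converges upward to 1 as landmarks accumulate
        (local single-landmark dips allowed; 3-point smoothing applied)."""
        data = sim_coord(n_specimens=10, n_landmarks=20, n_dims=3,
                         covariance=0.1, seed=5)
        result = lasec(data, SamplingSpec(n_iterations=40, seed=6))
        med = result.shape_median
        smooth = np.convolve(med, np.ones(3) / 3.0, mode="valid")
        assert np.all(np.diff(smooth) > -0.01)
        assert med[-1] == 1.0

    def test_too_few_specimens_rejected(self):
        coords = np.random.default_rng(0).standard_normal((2, 5, 2))
        with pytest.raises(LandmarkDataError, match="3 specimens"):
            lasec(coords)


class TestLandmarksAtThreshold:
    def _curves_with_medians(self, medians):
        medians = np.asarray(medians, dtype=float)
        n_k = len(medians)
        dummy = np.tile(medians, (2, 1))
        return SamplingCurves(
            landmark_counts=np.arange(3, 3 + n_k),
            shape_fits=dummy, size_fits=dummy,
            shape_median=medians, size_median=medians,
            threshold_table={}, landmark_orders=np.zeros((2, 3 + n_k - 1),
                                                         dtype=int),
        )

    def test_first_crossing(self):
        curves = self._curves_with_medians([0.50, 0.80, 0.92, 0.96, 1.0])
        assert landmarks_at_threshold(curves, 0.95) == 6

    def test_final_point_reaches_extreme_threshold(self):
        curves = self._curves_with_medians([0.5, 0.7, 0.9, 0.98, 1.0])
        assert landmarks_at_threshold(curves, 0.999) == 7

    def test_minimum_possible_count(self):
        curves = self._curves_with_medians([0.95, 0.97, 1.0])
        assert landmarks_at_threshold(curves, 0.90) == 3

    def test_unreachable_returns_none(self):
        curves = self._curves_with_medians([0.2, 0.4, 0.6])
        assert landmarks_at_threshold(curves, 0.90) is None

    def test_invalid_threshold_rejected(self, curves):
        for bad in (0.0, 1.0, 1.5, -0.1):
            with pytest.raises(LandmarkDataError):
                landmarks_at_threshold(curves, bad)

    def test_threshold_table_consistent_with_function(self, curves):
        for t, entry in curves.threshold_table.items():
            assert entry["shape"] == landmarks_at_threshold(curves, t,
                                                            "shape")
            assert entry["size"] == landmarks_at_threshold(curves, t, "size")


class TestInformedSubsample:
    def test_all_landmarks_give_perfect_fit(self, small_dataset):
        shape, size = informed_subsample_fit(small_dataset, list(range(8)))
        assert shape.fit == pytest.approx(1.0, abs=1e-10)
        assert size.fit == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_subset_scores_zero_with_warning(self):
        coords = np.random.default_rng(1).standard_normal((5, 6, 2))
        coords[:, :3, :] = 0.25  # first three landmarks coincide everywhere
        data = LandmarkConfigurationSet(coords=coords)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            shape, size = informed_subsample_fit(data, [0, 1, 2])
        assert shape.fit == 0.0
        assert size.fit == 0.0

    def test_duplicate_indices_rejected(self, small_dataset):
        with pytest.raises(LandmarkDataError, match="duplicate"):
            informed_subsample_fit(small_dataset, [0, 0, 1])

    def test_variance_informed_subset_beats_random_median(self):
        """On data whose shape variation is concentrated in a few landmarks,
        choosing those landmarks outperforms the median of random subsets of
        the same size."""
        base = sim_coord(n_specimens=12, n_landmarks=15, n_dims=2,
                         covariance=0.0, seed=8)
        coords = base.coords * 0.25
        coords[:, :6, :] *= 8.0  # landmarks 0-5 carry most shape variation
        data = LandmarkConfigurationSet(coords=coords)
        parent = gpa(data)
        aligned = parent.shape_vars.reshape(12, 15, 2)
        per_landmark_var = aligned.var(axis=0).sum(axis=1)
        k = 6
        keep = np.argsort(per_landmark_var)[-k:]
        informed, _ = informed_subsample_fit(data, keep.tolist())
        curves = lasec(data, SamplingSpec(n_iterations=30, seed=9))
        j = int(np.nonzero(curves.landmark_counts == k)[0][0])
        assert informed.fit >= curves.shape_median[j]


class TestEstimator:
    def test_fit_exposes_curves(self):
        data = sim_coord(n_specimens=8, n_landmarks=6, n_dims=2,
                         covariance=0.1, seed=21)
        est = LandmarkSamplingCurve(n_iterations=12, random_state=5)
        est.fit(data)
        assert est.shape_fits_.shape == (12, 4)
        assert est.landmarks_at_threshold(0.95, "shape") in (3, 4, 5, 6)
        assert est.threshold_table_ == est.curves_.threshold_table

    def test_matches_functional_api(self):
        data = sim_coord(n_specimens=8, n_landmarks=6, n_dims=2,
                         covariance=0.1, seed=21)
        est = LandmarkSamplingCurve(n_iterations=12, random_state=5).fit(data)
        func = lasec(data, SamplingSpec(n_iterations=12, seed=5))
        assert np.array_equal(est.shape_fits_, func.shape_fits)

    def test_sklearn_param_interface(self):
        est = LandmarkSamplingCurve(n_iterations=50, random_state=1)
        params = est.get_params()
        assert params["n_iterations"] == 50
        est.set_params(n_iterations=20)
        assert est.n_iterations == 20
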