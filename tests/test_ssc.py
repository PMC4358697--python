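"""The spurious-self-correlation randomization test.

The permutation machinery is checked against three independent oracles: the
closed-form all-equal-distance limit (every null slope exactly -1), the
exhaustive enumeration of all n! permutations at n = 4, and a per-replicate
refit with the general OLS routine using the same permutations the vectorized
path draws.
"""

import itertools
import math

import numpy as np
import pytest

from ratedecay import (
    DegenerateFitError,
    SyntheticConfig,
    ValidationError,
    distances,
    loglog_fit,
    loglog_fit_xy,
    simulate,
    ssc_randomization,
    ssc_report,
)

from conftest import make_dataset, make_record


def dataset_from_arrays(times, rates):
    return make_dataset(
        *[make_record(rate=float(r), calibration_time=float(t))
          for t, r in zip(times, rates)]
    )


class TestDistances:
    def test_distance_is_rate_times_time(self):
        ds = make_dataset(make_record(rate=1e-8, calibration_time=1e6))
        assert distances(ds) == pytest.approx([1e-2])

    def test_elementwise_products_match_brute_force(self, rng):
        times = 10 ** rng.uniform(0, 9, 30)
        rates = 10 ** rng.uniform(-10, -6, 30)
        ds = dataset_from_arrays(times, rates)
        assert distances(ds) == pytest.approx(times * rates, rel=1e-15)

    def test_extreme_published_magnitudes_stay_finite(self):
        ds = make_dataset(
            make_record(rate=1.78e-10, calibration_time=26000.0),
            make_record(rate=2.31e-6, calibration_time=6.0),
        )
        d = distances(ds)
        assert np.all(np.isfinite(d)) and np.all(d > 0)


class TestSscRandomization:
    def test_all_equal_distances_give_slope_exactly_minus_one(self):
        # power-of-two times make d_i = (0.01 / t) * t bit-identical, so the
        # closed-form limit (every permuted slope = -1) holds exactly
        times = 2.0 ** np.arange(1, 21)
        rates = 0.01 / times  # d_i = 0.01 for every record
        res = ssc_randomization(dataset_from_arrays(times, rates), B=200, seed=3,
                                keep_slopes=True)
        assert np.all(res.null_slopes == -1.0)
        assert res.mean_null_slope == -1.0
        # and the direct fit of such data has R^2 = 1
        fit = loglog_fit(dataset_from_arrays(times, rates))
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_vectorized_slopes_equal_per_replicate_refits(self):
        ds = simulate(SyntheticConfig(n=12, seed=4))
        B, seed = 50, 11
        res = ssc_randomization(ds, B=B, seed=seed, keep_slopes=True)
        log_t = np.log10([r.calibration_time for r in ds])
        log_d = np.log10(distances(ds))
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.broadcast_to(log_d, (B, log_d.size)), axis=1)
        refit = np.array([loglog_fit_xy(log_t, p - log_t).slope for p in perms])
        assert res.null_slopes == pytest.approx(refit, rel=1e-12)

    def test_sampled_distribution_converges_to_exhaustive_enumeration(self):
        """At n = 4 the 24-permutation null is enumerable exactly; the sampled
        ECDF must approach it in sup-norm."""
        ds = simulate(SyntheticConfig(n=4, seed=9))
        log_t = np.log10([r.calibration_time for r in ds])
        log_d = np.log10(distances(ds))
        exact = np.sort([
            loglog_fit_xy(log_t, np.array(p) - log_t).slope
            for p in itertools.permutations(log_d)
        ])
        res = ssc_randomization(ds, B=20_000, seed=1, keep_slopes=True)
        grid = np.unique(exact)
        ecdf_exact = np.searchsorted(exact, grid, side="right") / exact.size
        sampled = np.sort(res.null_slopes)
        ecdf_sampled = np.searchsorted(sampled, grid + 1e-12, side="right") / sampled.size
        # DKW bound at B = 20,000 and alpha = 1e-3 is ~0.014
        assert np.max(np.abs(ecdf_exact - ecdf_sampled)) < 0.025

    def test_permutation_preserves_distance_multiset(self):
        ds = simulate(SyntheticConfig(n=8, seed=2))
        log_d = np.log10(distances(ds))
        rng = np.random.default_rng(5)
        perms = rng.permuted(np.broadcast_to(log_d, (40, log_d.size)), axis=1)
        for row in perms:
            assert np.sort(row) == pytest.approx(np.sort(log_d))

    def test_same_seed_is_bit_identical(self):
        ds = simulate(SyntheticConfig(n=30, seed=6))
        a = ssc_randomization(ds, B=500, seed=42, keep_slopes=True)
        b = ssc_randomization(ds, B=500, seed=42, keep_slopes=True)
        assert a.mean_null_slope == b.mean_null_slope
        assert a.empirical_p == b.empirical_p
        assert np.array_equal(a.null_slopes, b.null_slopes)

    def test_empirical_p_floor_and_range(self):
        ds = simulate(SyntheticConfig(n=50, seed=8))
        res = ssc_randomization(ds, B=999, seed=0)
        assert 1 / 1000 <= res.empirical_p <= 1.0

    def test_mean_null_slope_near_minus_one_for_wide_time_spans(self):
        ds = simulate(SyntheticConfig(n=150, seed=12, log10_time_range=(0.0, 7.0)))
        res = ssc_randomization(ds, B=10_000, seed=3)
        assert abs(res.mean_null_slope - (-1.0)) < 0.02

    @pytest.mark.parametrize("n,B", [(2, 10), (5, 0)])
    def test_preconditions(self, n, B):
        ds = simulate(SyntheticConfig(n=n, seed=1))
        with pytest.raises((DegenerateFitError, ValidationError)):
            ssc_randomization(ds, B=B, seed=0)


class TestSscReport:
    def test_strong_time_dependence_rejects_both_tests(self):
        ds = simulate(SyntheticConfig(n=50, beta=-0.5, sigma=0.05, seed=21))
        rep = ssc_report(ds, B=999, seed=7)
        assert rep.empirical_p == pytest.approx(1 / 1000)
        assert rep.p_slope_vs_minus1 < 1e-6
        assert rep.rejects_ssc_null is True

    def test_pure_self_correlation_is_not_rejected_systematically(self):
        """Under the generative SSC null the parametric slope=-1 test should
        retain its nominal size; spot-check a handful of datasets."""
        rejections = 0
        for seed in range(20):
            ds = simulate(SyntheticConfig(n=100, scenario="ssc_null", seed=seed))
            rep = ssc_report(ds, B=499, seed=seed)
            rejections += rep.rejects_ssc_null
        assert rejections <= 4  # ~5% nominal; generous small-sample margin

    def test_report_carries_observed_fit_context(self):
        ds = simulate(SyntheticConfig(n=40, seed=13))
        fit = loglog_fit(ds, subset_label="coding")
        rep = ssc_report(ds, fit, B=99, seed=1)
        assert rep.subset_label == "coding"
        assert rep.observed_slope == pytest.approx(fit.slope)
        assert not math.isnan(rep.p_slope_vs_minus1)
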