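"""Smoothing, Bartlett-corrected and permutation Friedman tests, post hoc,
bootstrap, distributional distances."""

import math

import numpy as np
import pytest
from scipy import stats as ss

from abcells.stats import (
    SeriesPanel,
    bootstrap_ci,
    conover_holm,
    distribution_distance,
    effective_sample_size,
    friedman_neff,
    friedman_permutation,
    friedman_statistic,
    lag1_autocorrelation,
    moving_average,
    sliding_scan,
)
from abcells.synth import gen_grouped_series


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(30, 3.3), 15), 3.3)

    def test_ramp_first_window_mean(self):
        out = moving_average(np.arange(1.0, 21.0), 15)
        assert out[0] == pytest.approx(8.0)
        assert len(out) == 6

    def test_full_length_window_is_global_mean(self):
        x = np.array([1.0, 2.0, 6.0])
        out = moving_average(x, 3)
        assert out.shape == (1,)
        assert out[0] == pytest.approx(3.0)

    @pytest.mark.parametrize("w", [0, 25])
    def test_invalid_window_rejected(self, w):
        with pytest.raises(ValueError):
            moving_average(np.arange(20.0), w)


class TestAutocorrelation:
    def test_alternating_series(self):
        assert lag1_autocorrelation([1.0, -1.0, 1.0, -1.0]) == pytest.approx(-0.75)

    def test_long_ar1_recovers_phi(self):
        rng = np.random.default_rng(0)
        x = np.zeros(5000)
        for t in range(1, 5000):
            x[t] = 0.6 * x[t - 1] + rng.normal()
        assert lag1_autocorrelation(x) == pytest.approx(0.6, abs=0.05)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            lag1_autocorrelation(np.full(10, 2.0))


class TestEffectiveSampleSize:
    @pytest.mark.parametrize("n,q,expected", [(15, 0.0, 15.0), (15, 0.5, 5.0)])
    def test_closed_form(self, n, q, expected):
        assert effective_sample_size(n, q) == pytest.approx(expected)

    def test_extreme_autocorrelation_stays_positive(self):
        n_eff = effective_sample_size(15, 0.999)  # clamped to 0.99
        assert 0 < n_eff == pytest.approx(15 / 199, rel=1e-9)

    def test_monotone_decreasing_in_q(self):
        vals = [effective_sample_size(20, q) for q in np.linspace(0, 0.9, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestFriedman:
    def test_tied_panel_stat_zero_p_one(self):
        base = np.random.default_rng(0).normal(size=15)
        panel = np.tile(base, (4, 1))  # identical treatments
        stat, df, p, n_eff = friedman_neff(panel)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_classical_statistic_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            panel = rng.normal(size=(4, 15))
            stat, _ = friedman_statistic(panel)
            ref = ss.friedmanchisquare(*panel)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)

    def test_zero_autocorrelation_reduces_to_classical(self):
        """When panel Q clamps to 0, the corrected p equals scipy's."""
        rng = np.random.default_rng(9)
        found = 0
        for _ in range(50):
            panel = rng.normal(size=(4, 15))
            qs = [lag1_autocorrelation(row) for row in panel]
            if np.mean(qs) > 0:
                continue
            found += 1
            _, _, p, n_eff = friedman_neff(panel)
            assert n_eff == pytest.approx(15.0)
            assert p == pytest.approx(ss.friedmanchisquare(*panel).pvalue, abs=1e-9)
        assert found >= 5

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(2)
        panel = rng.normal(size=(4, 15))
        panel[2] += 10.0  # one treatment shifted by 10 SD
        _, _, p, _ = friedman_neff(panel)
        assert p < 0.001

    def test_permutation_identical_treatments_p_one(self):
        panel = np.tile(np.arange(10.0), (3, 1))
        assert friedman_permutation(panel, 200, seed=0) == pytest.approx(1.0)

    def test_permutation_minimum_is_add_one_bound(self):
        panel = np.vstack([np.zeros(15), np.ones(15), np.full(15, 2.0),
                           np.full(15, 3.0)])
        p = friedman_permutation(panel, 1000, seed=1)
        assert p == pytest.approx(1 / 1001)

    def test_permutation_reproducible_with_seed(self):
        rng = np.random.default_rng(4)
        panel = rng.normal(size=(4, 12))
        assert friedman_permutation(panel, 500, seed=7) == friedman_permutation(
            panel, 500, seed=7
        )


class TestConoverHolm:
    def test_identical_treatments_nothing_significant(self):
        panel = np.tile(np.arange(12.0), (4, 1))
        adj = conover_holm(panel).to_numpy()
        off = adj[~np.isnan(adj)]
        assert np.all(off >= 0.99)

    def test_deviant_treatment_has_smallest_adjusted_p(self):
        rng = np.random.default_rng(6)
        panel = rng.normal(size=(4, 15))
        panel[1] += 8.0
        adj = conover_holm(panel)
        pairs = {
            (i, j): adj.iloc[i, j]
            for i in range(4)
            for j in range(i + 1, 4)
        }
        deviant = sorted(p for (i, j), p in pairs.items() if 1 in (i, j))
        others = sorted(p for (i, j), p in pairs.items() if 1 not in (i, j))
        assert max(deviant) < min(others)

    def test_holm_adjustment_never_below_raw(self):
        # Holm is a step-down maximum: adjusted p >= raw p
        rng = np.random.default_rng(8)
        panel = rng.normal(size=(5, 12))
        ranks = np.apply_along_axis(ss.rankdata, 1, panel.T)
        adj = conover_holm(panel)
        # recompute raw Conover p and compare
        k, n = panel.shape
        rank_sums = ranks.sum(axis=0)
        a1 = (ranks**2).sum()
        c1 = n * k * (k + 1) ** 2 / 4
        t1 = (k - 1) * ((rank_sums - n * (k + 1) / 2) ** 2).sum() / (a1 - c1)
        dof = (n - 1) * (k - 1)
        scale = 2 * n * (a1 - c1) * (1 - t1 / (n * (k - 1))) / dof
        for i in range(k):
            for j in range(i + 1, k):
                t = abs(rank_sums[i] - rank_sums[j]) / math.sqrt(scale)
                raw = 2 * ss.t.sf(t, dof)
                assert adj.iloc[i, j] >= raw - 1e-12


class TestSlidingScan:
    def test_identical_series_yield_no_significant_windows(self):
        base = np.sin(np.linspace(0, 6, 60))
        panel = SeriesPanel(np.tile(base, (4, 1)) )
        res = sliding_scan(panel, ma_w=15, window_w=15, seed=0)
        assert all(r.posthoc is None for r in res)

    def test_changepoint_flagged_near_divergence(self):
        t_star = 40
        panel = gen_grouped_series(
            3, 90, group_offsets=[0.0, 0.0, 6.0], ar1_phi=0.0,
            noise_sd=0.5, changepoint=t_star, seed=3,
        )
        res = sliding_scan(panel, ma_w=15, window_w=15, seed=1)
        sig_starts = [
            r.start for r in res
            if not math.isnan(r.p_asymptotic) and r.p_asymptotic < 0.05
        ]
        assert sig_starts, "divergence never detected"
        # smoothed index s corresponds to raw frames [s, s+14]
        first_raw = sig_starts[0]
        assert t_star - 15 <= first_raw <= t_star + 15

    def test_non_overlapping_window_count(self):
        panel = gen_grouped_series(2, 75, seed=5)
        res = sliding_scan(panel, ma_w=15, window_w=15, step=15, seed=0)
        t_s = 75 - 15 + 1  # smoothed length
        assert len(res) == (t_s - 15) // 15 + 1

    def test_too_short_series_error_names_minimum(self):
        panel = SeriesPanel(np.random.default_rng(0).normal(size=(3, 20)))
        with pytest.raises(ValueError, match="29"):
            sliding_scan(panel, ma_w=15, window_w=15)


class TestDistances:
    def test_identical_samples_zero(self):
        x = np.arange(20.0)
        assert distribution_distance(x, x, "ks") == 0.0
        assert distribution_distance(x, x, "wasserstein") == 0.0

    def test_constant_shift_equals_wasserstein(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=300)
        assert distribution_distance(a, a + 2.5, "wasserstein") == pytest.approx(
            2.5, abs=1e-9
        )

    def test_separated_supports_ks_one(self):
        assert distribution_distance([0, 1, 2], [10, 11, 12], "ks") == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            distribution_distance([], [1.0])


class TestBootstrap:
    def test_constant_sample_degenerate_ci(self):
        r = bootstrap_ci(np.full(10, 4.2), n_resamples=200, seed=0)
        assert r.lower == r.estimate == r.upper == pytest.approx(4.2)

    def test_level_zero_collapses_to_point_estimate(self):
        r = bootstrap_ci([1.0, 2.0, 3.0], level=0.0, seed=0)
        assert r.lower == r.estimate == r.upper == pytest.approx(2.0)

    def test_seeded_reproducibility(self):
        x = np.random.default_rng(2).normal(size=50)
        a = bootstrap_ci(x, 1000, seed=11)
        b = bootstrap_ci(x, 1000, seed=11)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_interval_brackets_estimate(self):
        x = np.random.default_rng(3).normal(size=80)
        r = bootstrap_ci(x, 2000, seed=5)
        assert r.lower <= r.estimate <= r.upper


class TestPermutationAsymptoticAgreement:
    def test_white_noise_panels_agree_in_median(self):
        """On raw white-noise panels the chi-square and permutation
        references give close p-values (median gap below 0.05)."""
        rng = np.random.default_rng(17)
        gaps = []
        for i in range(100):
            panel = rng.normal(size=(4, 15))
            _, _, p_asym, _ = friedman_neff(panel)
            p_perm = friedman_permutation(panel, 1000, seed=i)
            if not math.isnan(p_asym):
                gaps.append(abs(p_asym - p_perm))
        assert np.median(gaps) < 0.05
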