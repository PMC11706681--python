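"""Burst detection, Poisson nulls and periodogram analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rootmitosis import (
    FrameSeries,
    burst_threshold,
    compare_to_poisson,
    counts_per_frame,
    detect_bursts,
    fit_poisson_tail,
    mode_matched_poisson,
    periodogram,
    simulate_table,
    top_periods,
)
from rootmitosis.synthetic import intact_defaults, regenerating_defaults
from rootmitosis.temporal import average_periodograms, white_noise_threshold


def _series(counts, dt=0.25):
    return FrameSeries("r1", "intact", np.asarray(counts), dt)


class TestCountsPerFrame:
    def test_direct_count_with_zero_fill(self, tiny_table):
        s = counts_per_frame(tiny_table, "intact_1")
        assert list(s.counts) == [2, 0, 1, 0]
        assert s.condition == "intact"

    def test_unknown_root_raises(self, tiny_table):
        with pytest.raises(KeyError):
            counts_per_frame(tiny_table, "nope")

    def test_counts_conserve_events_on_simulated_table(self):
        t = simulate_table(intact_defaults(2), regenerating_defaults(2), 2)
        for root in t.root_ids:
            s = counts_per_frame(t, root)
            assert s.counts.sum() == len(t.for_root(root))
            assert len(s) == t.n_frames


class TestBurstThreshold:
    def test_hand_computed_example(self):
        # mean 4, sample SD 2 -> threshold 6
        assert burst_threshold(_series([2, 4, 6])) == pytest.approx(6.0)

    def test_constant_series_threshold_equals_constant(self):
        assert burst_threshold(_series([7, 7, 7, 7])) == pytest.approx(7.0)

    def test_pooling_across_roots(self):
        a, b = _series([2, 4, 6]), _series([2, 4, 6])
        pooled = burst_threshold([a, b])
        # pooled SD (n=6, ddof=1) is slightly below the per-series value
        assert pooled == pytest.approx(4.0 + np.std([2, 4, 6] * 2, ddof=1))

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            burst_threshold([])

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=30),
           st.integers(min_value=0, max_value=20))
    @settings(max_examples=50, derandomize=True)
    def test_shift_consistency(self, counts, c):
        base = burst_threshold(_series(counts))
        shifted = burst_threshold(_series([x + c for x in counts]))
        assert shifted == pytest.approx(base + c)


class TestDetectBursts:
    def test_single_burst_above_threshold(self):
        b = detect_bursts(_series([3, 3, 30, 3]), 16.1)
        assert b.bursts == [(2, 30)]

    def test_zero_threshold_marks_every_nonzero_frame(self):
        b = detect_bursts(_series([0, 1, 0, 5]), 0.0)
        assert b.bursts == [(1, 1), (3, 5)]

    def test_all_below_threshold_gives_empty_set(self):
        assert len(detect_bursts(_series([1, 2, 3]), 10.0)) == 0

    def test_threshold_is_inclusive(self):
        assert detect_bursts(_series([2, 4, 6]), 6.0).bursts == [(2, 6)]


class TestPoissonNulls:
    @pytest.mark.parametrize("mode", [0, 11, 13])
    def test_mode_matched_rate_has_requested_argmax(self, mode):
        null = mode_matched_poisson(mode)
        assert null.lam == mode + 0.5
        k = np.arange(0, mode + 50)
        assert int(k[np.argmax(null.pmf(k))]) == mode

    def test_negative_mode_rejected(self):
        with pytest.raises(ValueError):
            mode_matched_poisson(-1)

    def test_pmf_sums_to_one(self):
        null = mode_matched_poisson(11)
        assert null.pmf(np.arange(0, 200)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_tail_mle_recovers_rate(self, rng):
        # rejection-sample Poisson(6) truncated to >= 8, then refit
        draws = rng.poisson(6.0, size=200_000)
        sample = draws[draws >= 8][:5000]
        null = fit_poisson_tail(sample, 8)
        assert null.lam == pytest.approx(6.0, rel=0.05)

    def test_tail_mle_rejects_values_below_support(self):
        with pytest.raises(ValueError):
            fit_poisson_tail([3, 9, 10], 8)


class TestCompareToPoisson:
    def test_constant_sample_matches_closed_form(self):
        null = mode_matched_poisson(11)
        cmp_ = compare_to_poisson([11] * 40, null)
        expected = max(1.0 - null.cdf(11), null.cdf(10))
        assert cmp_.d_stat == pytest.approx(float(expected), abs=1e-12)

    def test_self_consistency_for_large_poisson_sample(self, rng):
        sample = rng.poisson(11.5, size=10_000)
        cmp_ = compare_to_poisson(sample, mode_matched_poisson(11))
        assert cmp_.d_stat < 0.02

    def test_bimodal_sample_is_far_from_poisson(self):
        sample = [3] * 50 + [30] * 50
        cmp_ = compare_to_poisson(sample, mode_matched_poisson(11))
        assert cmp_.d_stat > 0.3
        assert cmp_.p_value < 1e-6

    def test_truncated_null_matches_tail_sample(self, rng):
        draws = rng.poisson(6.0, size=100_000)
        sample = draws[draws >= 8][:2000]
        cmp_ = compare_to_poisson(sample, fit_poisson_tail(sample, 8), min_size=8)
        assert cmp_.p_value > 0.05

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            compare_to_poisson([], mode_matched_poisson(5))


class TestPeriodogram:
    def test_constant_series_has_zero_power(self):
        pg = periodogram(_series([5] * 64))
        assert np.allclose(pg.psd, 0.0, atol=1e-18)

    def test_exact_bin_cosine_peaks_at_its_period(self):
        # 24 h is exactly bin 7 of a 168 h record: unique top peak at 24.0
        t = np.arange(672) * 0.25
        x = 10 + 4 * np.cos(2 * np.pi * t / 24.0)
        pg = periodogram(_series(x))
        assert top_periods(pg, 1)[0] == pytest.approx(24.0)
        assert pg.peaks[0][1] > 10 * pg.peaks[1][1] if len(pg.peaks) > 1 else True

    def test_parseval_identity(self, rng):
        for n in (64, 101, 672):
            x = rng.poisson(5.0, size=n).astype(float)
            pg = periodogram(_series(x))
            assert np.sum(pg.psd) * pg.df == pytest.approx(np.var(x), rel=1e-8)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            periodogram(_series([1, 2, 3]))

    def test_period_grid_decreases_with_frequency(self):
        pg = periodogram(_series(np.arange(32, dtype=float)))
        assert np.all(np.diff(pg.period_h) < 0)
        assert np.all(pg.psd >= 0)

    def test_two_sinusoids_recovered_in_top_two(self, rng):
        t = np.arange(672) * 0.25
        x = 8 + 4 * np.cos(2 * np.pi * t / 16.8) + 2 * np.cos(2 * np.pi * t / 10.5) \
            + rng.normal(0, 0.5, 672)
        pg = periodogram(_series(x))
        tops = top_periods(pg, 2)
        assert sorted(round(p, 2) for p in tops) == [10.5, 16.8]

    def test_white_noise_peaks_stay_below_bonferroni_threshold(self):
        for seed in (0, 1, 2):
            # i.i.d. Poisson counts are spectrally white after mean removal
            x = np.random.default_rng(seed).poisson(5.0, 672).astype(float)
            pg = periodogram(_series(x))
            thr = white_noise_threshold(pg, alpha=0.01)
            tops = pg.peaks[:3]
            assert len(tops) == 3
            assert all(power < thr for _, power in tops)

    def test_averaging_requires_matching_grids(self):
        a = periodogram(_series(np.arange(32, dtype=float)))
        b = periodogram(_series(np.arange(64, dtype=float)))
        with pytest.raises(ValueError):
            average_periodograms([a, b])

    def test_average_of_identical_periodograms_is_identity(self):
        a = periodogram(_series(np.arange(32, dtype=float)))
        avg = average_periodograms([a, a])
        assert np.allclose(avg.psd, a.psd)
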