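"""Cross-correlogram/jitter and coincidence/dither surrogate machinery."""

import numpy as np
import pytest

from iedflow import (SurrogateBand, ccg_significant, coincidence_series,
                     coincidence_significant, cross_correlogram,
                     dither_threshold, gen_correlated_pair, jitter_band,
                     pair_eligible)

from conftest import make_events, make_train, poisson_train


def brute_force_ccg(ta, tb, max_lag_ms=100.0, bin_ms=1.0):
    diffs = (tb[None, :] - ta[:, None]).ravel() * 1000.0
    edges = np.arange(-max_lag_ms - bin_ms / 2.0,
                      max_lag_ms + bin_ms / 2.0 + 1e-9, bin_ms)
    return np.histogram(diffs, bins=edges)[0]


class TestCrossCorrelogram:
    def test_identical_trains_peak_at_zero(self, rng):
        a = poisson_train(5.0, (0.0, 60.0), rng)
        ccg = cross_correlogram(a, a)
        assert ccg.lags_ms[np.argmax(ccg.counts)] == 0.0
        assert ccg.counts[ccg.lags_ms == 0.0][0] >= a.n_spikes

    def test_shifted_train_peak_at_shift(self, rng):
        a = poisson_train(5.0, (0.0, 60.0), rng)
        b = make_train(a.times + 0.010, span=(0.0, 61.0))
        ccg = cross_correlogram(a, b, check_eligibility=False)
        assert ccg.lags_ms[np.argmax(ccg.counts)] == 10.0

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            a = poisson_train(10.0, (0.0, 30.0), rng)
            b = poisson_train(10.0, (0.0, 30.0), rng)
            ccg = cross_correlogram(a, b)
            assert np.array_equal(ccg.counts,
                                  brute_force_ccg(a.times, b.times))

    def test_eligibility_needs_over_100_spikes(self, rng):
        small = make_train(np.arange(50) * 0.1)
        big = poisson_train(5.0, (0.0, 60.0), rng)
        assert not pair_eligible(small, big)
        with pytest.raises(ValueError, match="ineligible"):
            cross_correlogram(small, big)


class TestJitterBand:
    def test_zero_sd_band_collapses_onto_observed(self, rng):
        a = poisson_train(5.0, (0.0, 60.0), rng)
        b = poisson_train(5.0, (0.0, 60.0), rng)
        ccg = cross_correlogram(a, b)
        band = jitter_band(a, b, sd_ms=0.0, n=50, seed=1)
        assert np.array_equal(band.lower, ccg.counts)
        assert np.array_equal(band.upper, ccg.counts)

    def test_reproducible_under_fixed_seed(self, rng):
        a = poisson_train(5.0, (0.0, 60.0), rng)
        b = poisson_train(5.0, (0.0, 60.0), rng)
        b1 = jitter_band(a, b, n=100, seed=42)
        b2 = jitter_band(a, b, n=100, seed=42)
        assert np.array_equal(b1.lower, b2.lower)
        assert np.array_equal(b1.upper, b2.upper)

    def test_band_ordering_enforced(self):
        with pytest.raises(ValueError, match="lower"):
            SurrogateBand(np.array([2.0]), np.array([1.0]), 10, 0.99)


class TestCcgSignificance:
    def band(self, n_bins, upper=10.0):
        return SurrogateBand(np.zeros(n_bins), np.full(n_bins, upper), 1000,
                             0.99)

    def test_counts_inside_band_not_significant(self, rng):
        a = poisson_train(5.0, (0.0, 60.0), rng)
        ccg = cross_correlogram(a, a)
        band = SurrogateBand(np.zeros(201), ccg.counts.astype(float) + 1,
                             1000, 0.99)
        res = ccg_significant(ccg, band)
        assert not res.significant and res.significant_lags_ms.size == 0

    def test_single_bin_above_band_is_significant(self, rng):
        a = poisson_train(5.0, (0.0, 60.0), rng)
        ccg = cross_correlogram(a, a)
        ccg.counts[:] = 0
        ccg.counts[ccg.lags_ms == 4.0] = 11
        res = ccg_significant(ccg, self.band(201))
        assert res.significant
        assert res.significant_lags_ms.tolist() == [4.0]
        assert res.peak_within_25ms

    def test_interval_excludes_origin_and_far_lags(self, rng):
        a = poisson_train(5.0, (0.0, 60.0), rng)
        ccg = cross_correlogram(a, a)
        ccg.counts[:] = 0
        for lag in (0.0, 1.0, -50.0, 80.0):
            ccg.counts[ccg.lags_ms == lag] = 99
        assert not ccg_significant(ccg, self.band(201)).significant

    def test_correlated_pair_detected_with_high_power(self):
        hits = 0
        for seed in range(10):
            a, b = gen_correlated_pair(5.0, 0.15, 3.0, (0.0, 300.0),
                                       seed=seed)
            ccg = cross_correlogram(a, b)
            band = jitter_band(a, b, n=1000, seed=seed + 1000)
            if ccg_significant(ccg, band).significant:
                hits += 1
        assert hits >= 9

    def test_independent_pair_usually_not_significant(self, rng):
        hits = 0
        for seed in range(10):
            a, b = gen_correlated_pair(5.0, 0.0, 3.0, (0.0, 300.0), seed=seed)
            ccg = cross_correlogram(a, b)
            band = jitter_band(a, b, n=1000, seed=seed + 2000)
            hits += ccg_significant(ccg, band).significant
        # 60 bins tested at ~0.5% each -> a few false alarms possible
        assert hits <= 4


class TestCoincidences:
    def setup_pair(self, rng, n_events=100, rate=5.0):
        peaks = 5.0 + np.arange(n_events) * 2.5
        span = (0.0, float(peaks[-1] + 5.0))
        ev = make_events(peaks)
        a = poisson_train(rate, span, rng, "a")
        b = poisson_train(rate, span, rng, "b")
        return a, b, ev

    def test_disjoint_firing_gives_zeros(self):
        peaks = np.array([10.0, 20.0])
        ev = make_events(peaks)
        a = make_train(peaks - 0.5, span=(0.0, 30.0))   # only before peaks
        b = make_train(peaks + 0.5, span=(0.0, 30.0))   # only after peaks
        series = coincidence_series(a, b, ev)
        assert np.all(series.counts == 0)

    def test_single_pair_lands_in_earlier_spike_bin(self):
        ev = make_events([10.0])
        a = make_train([9.900], span=(0.0, 20.0))   # latency -100 ms
        b = make_train([9.902], span=(0.0, 20.0))   # latency  -98 ms
        series = coincidence_series(a, b, ev)
        assert series.counts.sum() == 1
        (bin_ms,) = series.bin_centers_ms[series.counts > 0]
        assert bin_ms == -95.0  # bin [-100, -90) of the earlier spike

    def test_matches_brute_force(self, rng):
        a, b, ev = self.setup_pair(rng, n_events=40)
        series = coincidence_series(a, b, ev)
        expected = np.zeros(200, dtype=int)
        for p in ev.peak_times:
            la = (a.times[(a.times >= p - 1) & (a.times < p + 1)] - p) * 1e3
            lb = (b.times[(b.times >= p - 1) & (b.times < p + 1)] - p) * 1e3
            for x in la:
                for y in lb:
                    if abs(y - x) <= 2.5:
                        expected[int((min(x, y) + 1000.0) // 10.0)] += 1
        assert np.array_equal(series.counts, expected)

    def test_zero_dither_degenerates_to_observed(self, rng):
        a, b, ev = self.setup_pair(rng, n_events=30)
        series = coincidence_series(a, b, ev)
        thr = dither_threshold(a, b, ev, dither_halfwidth_ms=0.0, n=20,
                               seed=0)
        assert np.array_equal(thr, series.counts)

    def test_thresholds_nonnegative_and_bounded_by_counts(self, rng):
        # interpolated order statistics of integer counts: non-negative and
        # bracketed by observed surrogate count values
        a, b, ev = self.setup_pair(rng, n_events=30)
        thr = dither_threshold(a, b, ev, n=200, seed=3)
        assert np.all(thr >= 0)
        assert np.all(np.ceil(thr) - np.floor(thr) <= 1.0)

    def test_injected_id_window_burst_flagged(self, rng):
        peaks = 5.0 + np.arange(60) * 2.5
        span = (0.0, float(peaks[-1] + 5.0))
        ev = make_events(peaks)
        base_a = poisson_train(4.0, span, rng).times
        base_b = poisson_train(4.0, span, rng).times
        # exact co-firing 2 ms after every event peak
        a = make_train(np.unique(np.r_[base_a, peaks + 0.002]), span=span)
        b = make_train(np.unique(np.r_[base_b, peaks + 0.002]), span=span)
        series = coincidence_series(a, b, ev)
        thr = dither_threshold(a, b, ev, n=500, seed=4)
        res = coincidence_significant(series, thr)
        assert res.significant
        assert np.any((res.significant_bins_ms >= 0.0)
                      & (res.significant_bins_ms < 10.0))

    def test_all_zero_series_not_significant(self):
        ev = make_events([10.0, 20.0])
        a = make_train(ev.peak_times - 0.5, span=(0.0, 30.0))
        b = make_train(ev.peak_times + 0.5, span=(0.0, 30.0))
        series = coincidence_series(a, b, ev)
        thr = dither_threshold(a, b, ev, n=50, seed=5)
        assert not coincidence_significant(series, thr).significant


class TestGeneratedPairs:
    def test_full_injection_zero_jitter_identical(self):
        a, b = gen_correlated_pair(5.0, 1.0, 0.0, (0.0, 100.0), seed=0)
        assert np.array_equal(a.times, b.times)

    def test_central_peak_within_expected_width(self):
        a, b = gen_correlated_pair(5.0, 0.15, 3.0, (0.0, 600.0), seed=1)
        ccg = cross_correlogram(a, b)
        peak_lag = ccg.lags_ms[np.argmax(ccg.counts)]
        assert abs(peak_lag) <= 10.0  # sqrt(2)*3 ms jitter spread

    def test_surrogate_jitter_preserves_spike_counts(self, rng):
        # the band machinery resamples times but never adds/removes spikes;
        # with a flat comb the total correlogram mass is conserved exactly
        a = make_train(np.arange(200) * 0.35 + 1.0)
        b = make_train(np.arange(200) * 0.35 + 1.05)
        ccg = cross_correlogram(a, b)
        band = jitter_band(a, b, sd_ms=0.0, n=10, seed=0)
        assert band.upper.sum() == ccg.counts.sum()
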