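"""Quality filter, rate estimation, rasters/PSTH and modulation classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from iedflow import (DEFAULT_WINDOWS, classify_modulation, group_rate_test,
                     instantaneous_rate, isi_violation_fraction,
                     passes_quality, peri_event_raster, psth)

from conftest import make_events, make_train, poisson_train


class TestIsiViolations:
    def test_single_spike_is_zero(self):
        assert isi_violation_fraction(make_train([0.5])) == 0.0

    def test_direct_count(self):
        train = make_train([0.0, 0.0005, 1.0, 2.0])
        assert isi_violation_fraction(train) == pytest.approx(1.0 / 3.0)

    def test_quality_threshold_is_half_percent(self):
        # 1 violation among 250 intervals = 0.4% -> passes; 1/150 fails
        good = make_train(np.r_[np.arange(250) * 0.1, 24.9 + 5e-4])
        bad = make_train(np.r_[np.arange(150) * 0.1, 14.9 + 5e-4])
        assert passes_quality(good)
        assert not passes_quality(bad)


class TestInstantaneousRate:
    def test_empty_train_all_zero(self):
        trace = instantaneous_rate(make_train([], span=(0.0, 2.0)))
        assert np.all(trace.values == 0.0)

    def test_single_spike_peak_matches_gaussian_density(self):
        trace = instantaneous_rate(make_train([1.0], span=(0.0, 2.0)))
        peak_expected = 1.0 / (0.020 * np.sqrt(2.0 * np.pi))  # ~19.947 Hz
        assert trace.values.max() == pytest.approx(peak_expected, rel=1e-4)
        assert trace.times[np.argmax(trace.values)] == pytest.approx(1.0,
                                                                     abs=6e-4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_integral_equals_spike_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        train = make_train(np.unique(rng.uniform(0, 10, n)), span=(0.0, 10.0))
        trace = instantaneous_rate(train)
        assert trace.integral == pytest.approx(train.n_spikes, rel=1e-6)


class TestRasterAndPsth:
    def test_empty_train_gives_empty_lists(self):
        raster = peri_event_raster(make_train([], span=(0.0, 20.0)),
                                   make_events([5.0, 10.0]))
        assert raster.n_events == 2
        assert all(lat.size == 0 for lat in raster.latencies_ms)

    def test_spike_exactly_at_peak_included(self):
        raster = peri_event_raster(make_train([5.0], span=(0.0, 20.0)),
                                   make_events([5.0]))
        assert raster.latencies_ms[0].tolist() == [0.0]

    def test_events_too_close_to_span_edge_dropped(self):
        raster = peri_event_raster(make_train([1.0], span=(0.0, 20.0)),
                                   make_events([0.5, 10.0]))
        assert raster.n_events == 1 and raster.n_dropped_events == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        train = poisson_train(4.0, (0.0, 60.0), rng)
        peaks = np.sort(rng.uniform(2.0, 58.0, 6))
        peaks = peaks[np.r_[True, np.diff(peaks) > 1e-6]]
        raster = peri_event_raster(train, make_events(peaks))
        for lat, p in zip(raster.latencies_ms, peaks):
            expected = sorted((t - p) * 1000.0 for t in train.times
                              if p - 1.0 <= t < p + 1.0)
            assert np.allclose(lat, expected)

    def test_psth_conserves_total_count_and_flat_rate(self, rng):
        span = (0.0, 700.0)
        train = poisson_train(5.0, span, rng)
        peaks = np.arange(5.0, 695.0, 3.45)[:200]
        raster = peri_event_raster(train, make_events(peaks))
        centers, rate = psth(raster, bin_ms=10.0)
        assert centers.size == 200
        total = rate.sum() * raster.n_events * 0.010
        assert total == pytest.approx(raster.total_spikes, rel=1e-9)
        se = np.sqrt(5.0 / (raster.n_events * 0.010))
        assert np.all(np.abs(rate - 5.0) <= 4 * se)

    def test_psth_empty_raster_zero(self):
        raster = peri_event_raster(make_train([], span=(0.0, 20.0)),
                                   make_events([10.0]))
        _, rate = psth(raster)
        assert np.all(rate == 0.0)

    def test_psth_bin_must_divide_width(self, rng):
        raster = peri_event_raster(poisson_train(5.0, (0.0, 20.0), rng),
                                   make_events([10.0]))
        with pytest.raises(ValueError):
            psth(raster, bin_ms=7.0)


def modulated_raster(rng, gains, n_events=200, base_rate=5.0):
    """Raster of a Poisson unit whose rate is gated per window."""
    latencies = []
    for _ in range(n_events):
        lat = []
        for (a, b), g in zip([(-1000.0, -600.0), DEFAULT_WINDOWS.baseline,
                              DEFAULT_WINDOWS.pre_id, DEFAULT_WINDOWS.id,
                              DEFAULT_WINDOWS.post_id, (400.0, 1000.0)],
                             [1.0, *gains, 1.0]):
            rate = base_rate * g
            n = rng.poisson(rate * (b - a) / 1000.0)
            lat.append(rng.uniform(a, b, n))
        latencies.append(np.sort(np.concatenate(lat)))
    from iedflow import PeriEventRaster
    return PeriEventRaster("u", latencies)


class TestClassifyModulation:
    def test_constant_rate_unit_unmodulated(self, rng):
        res = classify_modulation(modulated_raster(rng, [1.0, 1.0, 1.0, 1.0]))
        assert res.class_id == "none"
        assert res.class_pre == "none"
        assert res.class_post == "none"

    def test_id_gain_3_classified_increase(self, rng):
        res = classify_modulation(modulated_raster(rng, [1.0, 1.0, 3.0, 1.0]))
        assert res.class_id == "increase"
        assert res.ratio_id == pytest.approx(3.0, rel=0.25)

    def test_post_gain_04_classified_decrease(self, rng):
        res = classify_modulation(modulated_raster(rng, [1.0, 1.0, 1.0, 0.4]))
        assert res.class_post == "decrease"

    def test_pre_gain_detected_by_paired_test(self, rng):
        res = classify_modulation(modulated_raster(rng, [1.0, 2.5, 1.0, 1.0]))
        assert res.class_pre == "increase" and res.p_pre < 0.05
        res = classify_modulation(modulated_raster(rng, [1.0, 0.3, 1.0, 1.0]))
        assert res.class_pre == "decrease"

    def test_silent_baseline_uses_rate_floor(self, rng):
        from iedflow import PeriEventRaster
        # spikes only inside the ID window
        latencies = [np.array([0.0, 10.0]) for _ in range(20)]
        res = classify_modulation(PeriEventRaster("u", latencies))
        assert res.baseline_floored
        assert np.isfinite(res.ratio_id) and res.class_id == "increase"

    def test_requires_min_events(self, rng):
        with pytest.raises(ValueError, match="events"):
            classify_modulation(modulated_raster(rng, [1, 1, 1, 1],
                                                 n_events=5))

    def test_invariant_to_time_translation(self, rng):
        span = (0.0, 400.0)
        train = poisson_train(5.0, span, rng)
        peaks = np.arange(5.0, 395.0, 10.0)
        res1 = classify_modulation(peri_event_raster(train, make_events(peaks)))
        shifted = make_train(train.times + 1000.0, span=(1000.0, 1400.0))
        res2 = classify_modulation(
            peri_event_raster(shifted, make_events(peaks + 1000.0)))
        assert res1.window_rates_hz == res2.window_rates_hz
        assert (res1.class_id, res1.class_pre, res1.class_post) == \
            (res2.class_id, res2.class_pre, res2.class_post)


class TestGroupRateTest:
    def test_all_zero_differences(self):
        t, p, df = group_rate_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "right")
        assert t == 0.0 and p == 0.5 and df == 2

    def test_textbook_values(self):
        # differences (1, 2, 3): t = 2*sqrt(3), df = 2, right-tail p ~ 0.0371
        t, p, df = group_rate_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], "right")
        assert t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)
        assert df == 2
        assert p == pytest.approx(sstats.t.sf(2.0 * np.sqrt(3.0), 2), rel=1e-12)
        assert p == pytest.approx(0.0371, abs=5e-4)

    def test_df_is_group_size_minus_one(self, rng):
        for n in (2, 9, 24, 30):
            w = rng.normal(5, 1, n)
            b = rng.normal(4, 1, n)
            _, _, df = group_rate_test(w, b, "right")
            assert df == n - 1

    def test_left_tail_direction(self):
        t, p, _ = group_rate_test([1.0, 1.5, 0.5], [3.0, 3.1, 2.9], "left")
        assert t < 0 and p < 0.05

    def test_degenerate_constant_difference(self):
        t, p, df = group_rate_test([2.0, 3.0], [1.0, 2.0], "right")
        assert p == 0.0 and df == 1
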