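"""Pairwise spike synchrony: jittered cross-correlograms and coincidences.

Two complementary surrogate tests:

* Cross-correlogram test: spike-time lags ``t_b - t_a`` are histogrammed on
  1-ms bins over +-100 ms.  The null band is built from surrogates in which
  every spike of both trains receives an independent normal offset (SD 50
  ms); the 50-ms scale destroys millisecond structure while preserving rate
  co-modulation slower than that.  A pair is significant when at least one
  bin with ``|lag|`` in [1.5, 30] ms exceeds the upper bound of the
  99% band; whether a significant bin lies within +-25 ms of the origin is
  reported separately.

* Coincidence test: a coincidence is an ordered cross pair of spikes with
  ``|t_b - t_a| <= 2.5`` ms (5-ms total window), assigned to the 10-ms
  peri-event bin of the earlier spike.  Per-bin 99.9% thresholds come from
  surrogates in which every spike is dithered independently on a uniform
  +-5 ms interval.

Pair eligibility requires more than 100 spikes in each train.  Surrogate
randomness is drawn from a generator derived from a master seed plus a hash
of the pair's unit ids, so results do not depend on analysis order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .io_formats import EventSet, SpikeTrain, logger
from .unit_rates import DEFAULT_WINDOWS, PeriEventWindows, peri_event_raster

MIN_PAIR_SPIKES = 100  # strictly more spikes than this per train


def pair_rng(master_seed: int, unit_a: str, unit_b: str) -> np.random.Generator:
    """Named per-pair generator: master seed + CRC32 of the pair id."""
    pair_hash = zlib.crc32(f"{unit_a}|{unit_b}".encode())
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(pair_hash,)))


def pair_eligible(a: SpikeTrain, b: SpikeTrain,
                  min_spikes: int = MIN_PAIR_SPIKES) -> bool:
    return a.n_spikes > min_spikes and b.n_spikes > min_spikes


# ---------------------------------------------------------------------------
# Lag counting (shared by correlogram and coincidence code)
# ---------------------------------------------------------------------------

def _cross_lags(ta: np.ndarray, tb: np.ndarray, lo: float, hi: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """All lags ``t_b - t_a`` in ``[lo, hi)`` plus the a-spike of each pair.

    Both inputs must be sorted.  Returns ``(lags, a_times)`` aligned.
    """
    i0 = np.searchsorted(tb, ta + lo, side="left")
    i1 = np.searchsorted(tb, ta + hi, side="left")
    counts = i1 - i0
    total = int(counts.sum())
    if total == 0:
        return np.empty(0), np.empty(0)
    group = np.repeat(np.arange(counts.size), counts)
    within = np.arange(total) - np.r_[0, np.cumsum(counts)[:-1]][group]
    b_idx = i0[group] + within
    a_rep = ta[group]
    return tb[b_idx] - a_rep, a_rep


def _bin_counts(lags: np.ndarray, lo: float, bin_w: float, n_bins: int
                ) -> np.ndarray:
    idx = np.floor((lags - lo) / bin_w).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    return np.bincount(idx, minlength=n_bins)


# ---------------------------------------------------------------------------
# Cross-correlogram and jitter surrogates
# ---------------------------------------------------------------------------

@dataclass
class CrossCorrelogram:
    lags_ms: np.ndarray   # bin centres
    counts: np.ndarray
    n_ref: int
    n_tgt: int
    bin_ms: float = 1.0
    max_lag_ms: float = 100.0


@dataclass
class SurrogateBand:
    lower: np.ndarray
    upper: np.ndarray
    n_surrogates: int
    coverage: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("band bounds must satisfy lower <= upper")


def _ccg_counts(ta: np.ndarray, tb: np.ndarray, max_lag_s: float,
                bin_s: float, n_bins: int) -> np.ndarray:
    lo = -max_lag_s - bin_s / 2.0
    lags, _ = _cross_lags(ta, tb, lo, max_lag_s + bin_s / 2.0)
    return _bin_counts(lags, lo, bin_s, n_bins)


def cross_correlogram(a: SpikeTrain, b: SpikeTrain, max_lag_ms: float = 100.0,
                      bin_ms: float = 1.0, check_eligibility: bool = True
                      ) -> CrossCorrelogram:
    """Histogram of ordered spike-pair lags ``t_b - t_a`` (half-open bins)."""
    if check_eligibility and not pair_eligible(a, b):
        raise ValueError(
            f"pair {a.unit_id}/{b.unit_id} ineligible: needs > "
            f"{MIN_PAIR_SPIKES} spikes per train "
            f"(got {a.n_spikes}, {b.n_spikes})")
    n_bins = 2 * int(round(max_lag_ms / bin_ms)) + 1
    counts = _ccg_counts(a.times, b.times, max_lag_ms / 1000.0,
                         bin_ms / 1000.0, n_bins)
    centres = (np.arange(n_bins) - n_bins // 2) * bin_ms
    return CrossCorrelogram(centres, counts, a.n_spikes, b.n_spikes,
                            bin_ms, max_lag_ms)


def jitter_band(a: SpikeTrain, b: SpikeTrain, sd_ms: float = 50.0,
                n: int = 1000, coverage: float = 0.99,
                seed: int | np.random.Generator = 0,
                max_lag_ms: float = 100.0, bin_ms: float = 1.0,
                jitter_both: bool = True) -> SurrogateBand:
    """Per-bin empirical confidence band from normally jittered surrogates.

    Each surrogate adds an independent N(0, sd) offset to every spike of both
    trains (or only the second train when ``jitter_both`` is False), re-sorts
    and recomputes the correlogram; bounds are the empirical
    ``(1-coverage)/2`` and ``1-(1-coverage)/2`` quantiles per bin (linear
    interpolation between order statistics).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sd = sd_ms / 1000.0
    n_bins = 2 * int(round(max_lag_ms / bin_ms)) + 1
    counts = np.empty((n, n_bins), dtype=np.int64)
    max_lag_s, bin_s = max_lag_ms / 1000.0, bin_ms / 1000.0
    for k in range(n):
        ta = np.sort(a.times + rng.normal(0.0, sd, a.n_spikes)) \
            if jitter_both else a.times
        tb = np.sort(b.times + rng.normal(0.0, sd, b.n_spikes))
        counts[k] = _ccg_counts(ta, tb, max_lag_s, bin_s, n_bins)
    q = (1.0 - coverage) / 2.0
    lower, upper = np.quantile(counts, [q, 1.0 - q], axis=0)
    seed_val = seed if isinstance(seed, int) else None
    return SurrogateBand(lower, upper, n, coverage, seed_val)


@dataclass(frozen=True)
class CcgTestResult:
    significant: bool
    significant_lags_ms: np.ndarray
    peak_within_25ms: bool


def ccg_significant(ccg: CrossCorrelogram, band: SurrogateBand,
                    interval_ms: tuple[float, float] = (1.5, 30.0)
                    ) -> CcgTestResult:
    """Pair significance: any bin with |lag| in the interval above the band."""
    in_interval = ((np.abs(ccg.lags_ms) >= interval_ms[0])
                   & (np.abs(ccg.lags_ms) <= interval_ms[1]))
    above = ccg.counts > band.upper
    sig_bins = ccg.lags_ms[in_interval & above]
    return CcgTestResult(
        significant=bool(sig_bins.size > 0),
        significant_lags_ms=sig_bins,
        peak_within_25ms=bool(np.any(np.abs(sig_bins) <= 25.0)),
    )


# ---------------------------------------------------------------------------
# Coincidence analysis and dither surrogates
# ---------------------------------------------------------------------------

@dataclass
class CoincidenceSeries:
    bin_centers_ms: np.ndarray
    counts: np.ndarray
    window_ms: float
    bin_ms: float
    unit_a: str
    unit_b: str
    n_events: int


_EVENT_STRIDE_MS = 1.0e4  # combined-timeline spacing; >> raster width


def _combined_latencies(raster) -> np.ndarray:
    """Event-indexed latencies flattened onto a well-separated timeline."""
    parts = [lat + k * _EVENT_STRIDE_MS
             for k, lat in enumerate(raster.latencies_ms)]
    return np.concatenate(parts) if parts else np.empty(0)


def _coincidence_counts(ca: np.ndarray, cb: np.ndarray, window_ms: float,
                        bin_ms: float, halfwidth_ms: float) -> np.ndarray:
    """Coincidences per peri-event bin on combined timelines (ms units)."""
    half = window_ms / 2.0
    n_bins = int(round(2.0 * halfwidth_ms / bin_ms))
    lags, a_times = _cross_lags(ca, cb, -half, np.nextafter(half, np.inf))
    if lags.size == 0:
        return np.zeros(n_bins, dtype=np.int64)
    earlier = np.where(lags < 0, a_times + lags, a_times)
    lat = earlier - np.round(earlier / _EVENT_STRIDE_MS) * _EVENT_STRIDE_MS
    return _bin_counts(lat + halfwidth_ms, 0.0, bin_ms, n_bins)


def coincidence_series(a: SpikeTrain, b: SpikeTrain, events: EventSet,
                       window_ms: float = 5.0, bin_ms: float = 10.0,
                       halfwidth_ms: float = 1000.0) -> CoincidenceSeries:
    """Count near-coincident cross pairs per peri-event bin.

    A coincidence is an ordered pair with ``|t_b - t_a| <= window/2``
    within the same event's raster, assigned to the bin of the earlier spike.
    """
    ra = peri_event_raster(a, events, halfwidth_ms)
    rb = peri_event_raster(b, events, halfwidth_ms)
    if ra.n_events != rb.n_events:
        raise ValueError("rasters disagree on usable events; trains must "
                         "share a recording span")
    counts = _coincidence_counts(_combined_latencies(ra),
                                 _combined_latencies(rb),
                                 window_ms, bin_ms, halfwidth_ms)
    centres = -halfwidth_ms + (np.arange(counts.size) + 0.5) * bin_ms
    return CoincidenceSeries(centres, counts, window_ms, bin_ms,
                             a.unit_id, b.unit_id, ra.n_events)


def dither_threshold(a: SpikeTrain, b: SpikeTrain, events: EventSet,
                     dither_halfwidth_ms: float = 5.0, n: int = 1000,
                     p: float = 0.001, seed: int | np.random.Generator = 0,
                     window_ms: float = 5.0, bin_ms: float = 10.0,
                     halfwidth_ms: float = 1000.0) -> np.ndarray:
    """Per-bin ``1-p`` quantile of surrogate coincidence counts.

    Every spike of both units is independently dithered on a uniform
    ``+-dither_halfwidth_ms`` interval; latencies pushed outside the raster
    are clipped to the window edge (minus a vanishing offset), preserving
    per-train spike counts exactly.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ra = peri_event_raster(a, events, halfwidth_ms)
    rb = peri_event_raster(b, events, halfwidth_ms)
    ca0 = _combined_latencies(ra)
    cb0 = _combined_latencies(rb)
    base_a = np.round(ca0 / _EVENT_STRIDE_MS) * _EVENT_STRIDE_MS
    base_b = np.round(cb0 / _EVENT_STRIDE_MS) * _EVENT_STRIDE_MS
    n_bins = int(round(2.0 * halfwidth_ms / bin_ms))
    counts = np.empty((n, n_bins), dtype=np.int64)
    eps = 1e-6
    for k in range(n):
        da = ca0 + rng.uniform(-dither_halfwidth_ms, dither_halfwidth_ms,
                               ca0.size)
        db = cb0 + rng.uniform(-dither_halfwidth_ms, dither_halfwidth_ms,
                               cb0.size)
        da = np.clip(da, base_a - halfwidth_ms,
                     base_a + halfwidth_ms - eps * rng.uniform())
        db = np.clip(db, base_b - halfwidth_ms,
                     base_b + halfwidth_ms - eps * rng.uniform())
        counts[k] = _coincidence_counts(np.sort(da), np.sort(db),
                                        window_ms, bin_ms, halfwidth_ms)
    return np.quantile(counts, 1.0 - p, axis=0)


@dataclass(frozen=True)
class CoincidenceTestResult:
    significant: bool
    significant_bins_ms: np.ndarray


def coincidence_significant(series: CoincidenceSeries,
                            thresholds: np.ndarray,
                            windows: PeriEventWindows = DEFAULT_WINDOWS
                            ) -> CoincidenceTestResult:
    """Bins above threshold; overall flag if any lies in the pre-ID or ID window."""
    above = series.counts > thresholds
    sig_bins = series.bin_centers_ms[above]
    lo = windows.pre_id[0]
    hi = windows.id[1]
    overall = bool(np.any((sig_bins >= lo) & (sig_bins < hi)))
    return CoincidenceTestResult(overall, sig_bins)


def skip_ineligible(a: SpikeTrain, b: SpikeTrain) -> bool:
    """Log and report ineligibility (used by the pipeline)."""
    if pair_eligible(a, b):
        return False
    logger.info("pair %s/%s skipped: <= %d spikes in at least one train",
                a.unit_id, b.unit_id, MIN_PAIR_SPIKES)
    return True
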