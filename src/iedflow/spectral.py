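"""Morlet time-frequency analysis of peri-event LFP with baseline Z-scoring.

The complex Morlet wavelet at frequency ``f`` is a sinusoid windowed by a
Gaussian of standard deviation ``sigma = nco / (6 f)``; ``nco`` (default 5)
fixes the number of cycles and hence the time-frequency resolution
trade-off.  The kernel is normalized to unit area, so a pure tone of
amplitude ``A`` produces a flat response of modulus ``A/2`` at the tone
frequency regardless of ``f`` and the discrete argmax over frequencies is
unbiased.  Per-frequency scaling cancels identically in the baseline
Z-scores, so this choice does not affect any normalized quantity.

Power is ``|W|^2``.  For baseline correction the mean and SD of power are
computed per frequency over all events' baseline windows ([-600, -300) ms
before the peak), the mean is subtracted everywhere and the result scaled by
1/SD; the normalized maps are then averaged across events.  ``|Z| > 3.09``
corresponds to a one-sided normal tail of 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from statsmodels.stats.diagnostic import lilliefors

from .io_formats import EventSet, LfpSignal

Z_CRITICAL = 3.09  # one-sided standard-normal tail of ~0.001


@dataclass(frozen=True)
class MorletParams:
    freqs: np.ndarray = field(
        default_factory=lambda: np.arange(20.0, 300.0 + 1e-9, 2.0))
    nco: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        if self.nco <= 0:
            raise ValueError("nco must be > 0")
        if np.any(self.freqs <= 0):
            raise ValueError("frequencies must be > 0")

    def sigma(self, f: float) -> float:
        """Gaussian SD of the wavelet envelope at frequency f (nco = 6 f sigma)."""
        return self.nco / (6.0 * f)


@dataclass
class TFMap:
    """Time x frequency matrix, either raw power or baseline Z-scores."""

    times: np.ndarray            # s; absolute (power) or relative to peak (zscore)
    freqs: np.ndarray
    values: np.ndarray           # shape (n_freqs, n_times)
    mode: str                    # "power" | "zscore"
    valid: np.ndarray            # bool, same shape; False near edges
    baseline_window_ms: tuple[float, float] | None = None
    baseline_mean: np.ndarray | None = None
    baseline_sd: np.ndarray | None = None
    n_events: int = 0


def _wavelet_kernel(f: float, sigma: float, fs: float) -> np.ndarray:
    half = int(np.ceil(5.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-0.5 * (t / sigma) ** 2)
    gauss /= gauss.sum() / fs  # unit area
    return gauss * np.exp(2j * np.pi * f * t)


def _transform_row(x: np.ndarray, f: float, params: MorletParams,
                   fs: float) -> tuple[np.ndarray, int]:
    """Complex wavelet coefficients at one frequency; returns (W, half_support)."""
    sigma = params.sigma(f)
    kern = _wavelet_kernel(f, sigma, fs)
    w = sps.fftconvolve(x, kern, mode="same") / fs
    return w, (kern.size - 1) // 2


def morlet_transform(lfp: LfpSignal, params: MorletParams = MorletParams()
                     ) -> TFMap:
    """Wavelet power map of a whole trace; edge samples are marked invalid."""
    fs = lfp.fs
    if np.any(params.freqs >= fs / 2.0):
        raise ValueError("all frequencies must be below the Nyquist rate")
    fmin = params.freqs.min()
    if lfp.duration < 10.0 / fmin:
        raise ValueError("trace must cover >= 10 cycles of the lowest frequency")
    n = lfp.n_samples
    power = np.empty((params.freqs.size, n))
    valid = np.zeros((params.freqs.size, n), dtype=bool)
    for i, f in enumerate(params.freqs):
        w, half = _transform_row(lfp.samples, f, params, fs)
        power[i] = np.abs(w) ** 2
        if n > 2 * half:
            valid[i, half:n - half] = True
    return TFMap(lfp.times, params.freqs.copy(), power, "power", valid)


def _window_mask(rel_times_s: np.ndarray, window_ms: tuple[float, float]
                 ) -> np.ndarray:
    a, b = window_ms
    return (rel_times_s >= a / 1000.0) & (rel_times_s < b / 1000.0)


def _event_columns(tf: TFMap, events: EventSet, fs: float,
                   halfwidth_ms: float) -> tuple[np.ndarray, list[int]]:
    """Relative-time offsets and usable event centre indices for slicing."""
    half_n = int(round(halfwidth_ms / 1000.0 * fs))
    offsets = np.arange(-half_n, half_n + 1)
    centres = []
    n = tf.times.size
    for p in events.peak_times:
        c = int(round((p - tf.times[0]) * fs))
        if c - half_n < 0 or c + half_n >= n:
            continue
        if not tf.valid[:, c - half_n:c + half_n + 1].all():
            continue
        centres.append(c)
    return offsets, centres


def baseline_zscore(tf: TFMap, events: EventSet,
                    baseline_ms: tuple[float, float] = (-600.0, -300.0),
                    halfwidth_ms: float = 1000.0) -> TFMap:
    """Normalize a power map to baseline Z-scores and average across events.

    Baseline mean and SD are pooled per frequency over all events' baseline
    windows; frequencies with zero baseline SD are flagged invalid.
    Requires >= 2 events whose full peri-event window is valid.
    """
    if tf.mode != "power":
        raise ValueError("baseline_zscore expects a power map")
    fs = 1.0 / (tf.times[1] - tf.times[0])
    offsets, centres = _event_columns(tf, events, fs, halfwidth_ms)
    if len(centres) < 2:
        raise ValueError("need >= 2 events with a fully valid peri-event window")
    rel_times = offsets / fs
    base_cols = _window_mask(rel_times, baseline_ms)
    stack = np.stack([tf.values[:, c + offsets] for c in centres])  # (ev, f, t)
    pooled = stack[:, :, base_cols]                                 # (ev, f, tb)
    mean = pooled.mean(axis=(0, 2))
    sd = pooled.std(axis=(0, 2))
    ok = sd > 0
    z = np.zeros_like(stack)
    z[:, ok, :] = (stack[:, ok, :] - mean[ok, None]) / sd[ok, None]
    valid = np.broadcast_to(ok[:, None], (tf.freqs.size, rel_times.size)).copy()
    return TFMap(rel_times, tf.freqs.copy(), z.mean(axis=0), "zscore", valid,
                 baseline_ms, mean, sd, n_events=len(centres))


def event_zscore_map(lfp: LfpSignal, events: EventSet,
                     params: MorletParams = MorletParams(),
                     baseline_ms: tuple[float, float] = (-600.0, -300.0),
                     halfwidth_ms: float = 1000.0) -> TFMap:
    """Peri-event averaged Z-map computed one frequency at a time.

    Mathematically identical to ``baseline_zscore(morlet_transform(lfp), ...)``
    but never materializes the full time x frequency power map, so it scales
    to long recordings.
    """
    fs = lfp.fs
    if np.any(params.freqs >= fs / 2.0):
        raise ValueError("all frequencies must be below the Nyquist rate")
    half_n = int(round(halfwidth_ms / 1000.0 * fs))
    offsets = np.arange(-half_n, half_n + 1)
    rel_times = offsets / fs
    base_cols = _window_mask(rel_times, baseline_ms)
    n = lfp.n_samples
    fmax_half = int(np.ceil(5.0 * params.sigma(params.freqs.min()) * fs))
    centres = [int(round((p - lfp.t0) * fs)) for p in events.peak_times]
    centres = [c for c in centres
               if c - half_n - fmax_half >= 0 and c + half_n + fmax_half < n]
    if len(centres) < 2:
        raise ValueError("need >= 2 events with a fully valid peri-event window")
    zmean = np.empty((params.freqs.size, rel_times.size))
    means = np.empty(params.freqs.size)
    sds = np.empty(params.freqs.size)
    ok = np.ones(params.freqs.size, dtype=bool)
    for i, f in enumerate(params.freqs):
        w, _ = _transform_row(lfp.samples, f, params, fs)
        power = np.abs(w) ** 2
        stack = np.stack([power[c + offsets] for c in centres])
        pooled = stack[:, base_cols]
        means[i], sds[i] = pooled.mean(), pooled.std()
        if sds[i] == 0:
            ok[i] = False
            zmean[i] = 0.0
        else:
            zmean[i] = ((stack - means[i]) / sds[i]).mean(axis=0)
    valid = np.broadcast_to(ok[:, None],
                            (params.freqs.size, rel_times.size)).copy()
    return TFMap(rel_times, params.freqs.copy(), zmean, "zscore", valid,
                 baseline_ms, means, sds, n_events=len(centres))


def significant_tf_mask(tf: TFMap, z_crit: float = Z_CRITICAL,
                        two_sided: bool = True) -> np.ndarray:
    """Boolean mask of significant Z-score cells (invalid cells never flag)."""
    if tf.mode != "zscore":
        raise ValueError("significant_tf_mask expects a zscore map")
    mag = np.abs(tf.values) if two_sided else tf.values
    return (mag > z_crit) & tf.valid


@dataclass(frozen=True)
class HfoScore:
    peak_z: float
    peak_freq_hz: float
    peak_time_ms: float


def preid_hfo_score(tf: TFMap, band_hz: tuple[float, float] = (40.0, 120.0),
                    window_ms: tuple[float, float] = (-300.0, -50.0)
                    ) -> HfoScore:
    """Maximum Z over the high-frequency band x pre-event window."""
    if tf.mode != "zscore":
        raise ValueError("preid_hfo_score expects a zscore map")
    frow = (tf.freqs >= band_hz[0]) & (tf.freqs <= band_hz[1])
    if not frow.any():
        raise ValueError("band outside the analyzed frequencies")
    tcol = _window_mask(tf.times, window_ms)
    sub = np.where(tf.valid[np.ix_(frow, tcol)], tf.values[np.ix_(frow, tcol)],
                   -np.inf)
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    return HfoScore(float(sub[i, j]), float(tf.freqs[frow][i]),
                    float(tf.times[tcol][j] * 1000.0))


def baseline_coefficient_sample(lfp: LfpSignal, events: EventSet,
                                freq_hz: float,
                                params: MorletParams = MorletParams(),
                                baseline_ms: tuple[float, float] = (-600.0,
                                                                    -300.0)
                                ) -> np.ndarray:
    """Real parts of the wavelet coefficients pooled over baseline windows.

    For a Gaussian background these are normally distributed, which is what
    the KS check below assesses (power, being a squared modulus, is not).
    """
    fs = lfp.fs
    w, half = _transform_row(lfp.samples, freq_hz, params, fs)
    a, b = baseline_ms
    parts = []
    n = lfp.n_samples
    for p in events.peak_times:
        i0 = int(round((p - lfp.t0 + a / 1000.0) * fs))
        i1 = int(round((p - lfp.t0 + b / 1000.0) * fs))
        if i0 < half or i1 > n - half:
            continue
        parts.append(np.real(w[i0:i1]))
    if not parts:
        raise ValueError("no event has a valid baseline window")
    return np.concatenate(parts)


@dataclass(frozen=True)
class KsResult:
    statistic: float
    p_value: float
    reject: bool


def ks_normality(values: np.ndarray, alpha: float = 0.05) -> KsResult:
    """Kolmogorov-Smirnov normality check with estimated mean/SD.

    Because the reference normal's parameters are estimated from the sample,
    Lilliefors critical values are used rather than the plain KS table.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 10:
        raise ValueError("need >= 10 values")
    if np.ptp(values) == 0.0:
        raise ValueError("constant sample: normality test undefined")
    d, p = lilliefors(values, dist="norm", pvalmethod="table")
    return KsResult(float(d), float(p), bool(p < alpha))
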