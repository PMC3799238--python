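"""Ground-truth-labelled synthetic recordings for the discharge pipeline.

The generator emulates the statistical structure the analysis assumes:

* LFP: 1/f^alpha Gaussian background (spectral synthesis, robust SD
  normalized to ``lfp_scale_uv``) with embedded discharge templates -- a
  sharp Gaussian component (20-100 ms FWHM) with a biphasic dip, followed by
  a 200-500 ms slow half-wave -- at hard-core renewal event times (Poisson
  gaps plus a 2-s refractory, mean rate exactly as configured).  Optionally
  an amplitude-modulated 40-120 Hz oscillation in the pre-event window.
* Units: inhomogeneous Poisson spike trains sampled by thinning.  Each
  unit's rate is its baseline multiplied by a class-specific gain inside the
  class window around every true event (piecewise-constant gating, so
  per-window rates are analytically known).  A 1.5-ms absolute refractory
  period is enforced by deletion.
* Correlated pairs: common spikes copied from a hidden mother train with
  independent millisecond jitter, yielding a central cross-correlogram peak
  of width ~ sqrt(2) * jitter.

All randomness flows from ``master_seed`` through named substreams (lfp,
units, pairs), so each component can be regenerated independently and runs
are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (EventSet, LfpSignal, SpikeTrain, write_events,
                         write_lfp, write_spike_trains)
from .unit_rates import CLASS_WINDOWS

UNIT_CLASSES = ("none", "id_increase", "post_decrease", "pre_increase",
                "pre_decrease")

#: default class gains (rate multipliers inside the class window)
DEFAULT_GAINS = {"none": 1.0, "id_increase": 3.0, "post_decrease": 0.4,
                 "pre_increase": 2.5, "pre_decrease": 0.3}

_SUBSTREAM = {"lfp": 0, "units": 1, "pairs": 2}

EVENT_REFRACTORY_S = 2.0
SPIKE_REFRACTORY_S = 0.0015
EDGE_MARGIN_S = 2.0  # no events this close to the trace edges


@dataclass(frozen=True)
class UnitSpec:
    baseline_rate_hz: float
    unit_class: str = "none"
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate_hz <= 0 or self.gain <= 0:
            raise ValueError("rates and gains must be > 0")
        if self.unit_class not in UNIT_CLASSES:
            raise ValueError(f"unknown unit class {self.unit_class!r}")
        if self.unit_class == "id_increase" and self.gain < 2.0:
            raise ValueError("id_increase gain must be >= 2")
        if self.unit_class == "post_decrease" and self.gain > 0.5:
            raise ValueError("post_decrease gain must be <= 0.5")


@dataclass(frozen=True)
class PairSpec:
    unit_i: int
    unit_j: int
    injection_fraction: float
    injection_jitter_ms: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.injection_fraction <= 1.0:
            raise ValueError("injection_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PreIdBurst:
    """Amplitude-modulated pre-event oscillation (the 40-120 Hz signature)."""

    enabled: bool = False
    freq_hz: float = 90.0
    window_ms: tuple[float, float] = (-300.0, -50.0)
    # peak envelope amplitude in background robust SDs; the default is
    # calibrated so the averaged peri-event Z-map peaks around Z ~ 5-8,
    # the scale reported for pre-discharge 40-120 Hz oscillations
    amp_sd: float = 0.55


@dataclass
class SimConfig:
    duration_s: float = 600.0
    fs: float = 1000.0
    event_rate_hz: float = 0.07
    id_sharp_width_ms: float = 60.0   # FWHM of the sharp component, 20-100
    id_slow_width_ms: float = 350.0   # slow-wave duration, 200-500
    id_amp_snr: float = 8.0           # template peak / background robust SD
    noise_alpha: float = 1.0          # background spectral slope 1/f^alpha
    lfp_scale_uv: float = 25.0        # background robust SD in uV
    preid_burst: PreIdBurst = field(default_factory=PreIdBurst)
    units: list[UnitSpec] = field(default_factory=list)
    pairs: list[PairSpec] = field(default_factory=list)
    master_seed: int = 0
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        if not 20.0 <= self.id_sharp_width_ms <= 100.0:
            raise ValueError("id_sharp_width_ms must be in [20, 100]")
        if not 200.0 <= self.id_slow_width_ms <= 500.0:
            raise ValueError("id_slow_width_ms must be in [200, 500]")
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be >= 0")
        if self.event_rate_hz > 0 and 1.0 / self.event_rate_hz <= EVENT_REFRACTORY_S:
            raise ValueError("event rate too high for the 2-s refractory")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["preid_burst"] = PreIdBurst(**{**d["preid_burst"], "window_ms":
                                         tuple(d["preid_burst"]["window_ms"])})
        d["units"] = [UnitSpec(**u) for u in d["units"]]
        d["pairs"] = [PairSpec(**p) for p in d["pairs"]]
        return cls(**d)


def default_unit_specs(n_units: int = 40, seed: int = 0) -> list[UnitSpec]:
    """Unit mix mirroring the reported class proportions.

    30% discharge-window increase, 40% post-window decrease, 12%/18%
    pre-window increase/decrease; baseline rates drawn uniformly from the
    2-7 Hz range typical of hippocampal units.
    """
    counts = {
        "id_increase": round(0.30 * n_units),
        "post_decrease": round(0.40 * n_units),
        "pre_increase": round(0.12 * n_units),
        "pre_decrease": round(0.18 * n_units),
    }
    counts["none"] = n_units - sum(counts.values())
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    specs = []
    for cls_name in ("id_increase", "post_decrease", "pre_increase",
                     "pre_decrease", "none"):
        for _ in range(counts[cls_name]):
            rate = float(rng.uniform(2.0, 7.0))
            specs.append(UnitSpec(rate, cls_name, DEFAULT_GAINS[cls_name]))
    return specs


def _rng(cfg_seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(cfg_seed, spawn_key=(_SUBSTREAM[stream], index)))


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _pink_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    spectrum = amp * (rng.standard_normal(freqs.size)
                      + 1j * rng.standard_normal(freqs.size))
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    mad = np.median(np.abs(x - np.median(x)))
    return (x - np.median(x)) / (1.4826 * mad)


def id_template(cfg: SimConfig) -> tuple[np.ndarray, int]:
    """Discharge template in background-robust-SD units.

    Returns ``(waveform, peak_index)``; the waveform peak equals
    ``id_amp_snr`` exactly.
    """
    fs = cfg.fs
    sigma = cfg.id_sharp_width_ms / 1000.0 / 2.355  # FWHM -> SD
    slow_w = cfg.id_slow_width_ms / 1000.0
    t_lo, t_hi = -4.0 * sigma, 3.0 * sigma + slow_w
    t = np.arange(int(np.floor(t_lo * fs)), int(np.ceil(t_hi * fs)) + 1) / fs
    sharp = np.exp(-0.5 * (t / sigma) ** 2)
    dip = -0.35 * np.exp(-0.5 * ((t - 2.0 * sigma) / (1.3 * sigma)) ** 2)
    slow_start = 3.0 * sigma
    phase = np.clip((t - slow_start) / slow_w, 0.0, 1.0)
    slow = -0.25 * np.sin(np.pi * phase)
    wave = sharp + dip + slow
    wave *= cfg.id_amp_snr / np.max(np.abs(wave))
    peak_idx = int(np.argmax(wave))
    return wave, peak_idx


def _event_times(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Hard-core renewal times: 2-s refractory, mean rate exactly as asked."""
    r = cfg.event_rate_hz
    if r == 0.0:
        return np.empty(0)
    mean_gap_excess = 1.0 / r - EVENT_REFRACTORY_S
    t = EDGE_MARGIN_S
    times = []
    while True:
        t += EVENT_REFRACTORY_S + rng.exponential(mean_gap_excess)
        if t >= cfg.duration_s - EDGE_MARGIN_S:
            break
        times.append(t)
    return np.asarray(times)


def gen_lfp(cfg: SimConfig, seed: int | None = None
            ) -> tuple[LfpSignal, EventSet]:
    """Background + discharge templates (+ optional pre-event bursts).

    Returns the trace and the ground-truth events (peaks at template apex).
    """
    rng = _rng(cfg.master_seed if seed is None else seed, "lfp")
    n = int(round(cfg.duration_s * cfg.fs))
    x = _pink_noise(n, cfg.noise_alpha, rng)

    peaks = _event_times(cfg, rng)
    wave, peak_idx = id_template(cfg)
    sigma = cfg.id_sharp_width_ms / 1000.0 / 2.355
    onsets, offsets = [], []
    for p in peaks:
        i_peak = int(round(p * cfg.fs))
        i0 = i_peak - peak_idx
        x[i0:i0 + wave.size] += wave
        onsets.append(i_peak / cfg.fs - 2.0 * sigma)
        offsets.append(i_peak / cfg.fs + 3.0 * sigma
                       + cfg.id_slow_width_ms / 1000.0)

    if cfg.preid_burst.enabled and peaks.size:
        b = cfg.preid_burst
        w0, w1 = b.window_ms[0] / 1000.0, b.window_ms[1] / 1000.0
        n_win = int(round((w1 - w0) * cfg.fs))
        t_win = np.arange(n_win) / cfg.fs
        envelope = np.sin(np.pi * t_win / t_win[-1]) ** 2  # Hann-shaped
        for p in peaks:
            i0 = int(round((p + w0) * cfg.fs))
            phase = rng.uniform(0, 2 * np.pi)
            x[i0:i0 + n_win] += (b.amp_sd * envelope
                                 * np.sin(2 * np.pi * b.freq_hz * t_win + phase))

    peaks_grid = np.round(peaks * cfg.fs) / cfg.fs
    events = EventSet(
        peak_times=peaks_grid, onsets=np.asarray(onsets),
        offsets=np.asarray(offsets),
        amplitudes=np.full(peaks.size, cfg.id_amp_snr * cfg.lfp_scale_uv),
        channel_ids=np.array([cfg.channel_id] * peaks.size, dtype=object),
        source="imported",
    )
    lfp = LfpSignal(cfg.channel_id, cfg.fs, x * cfg.lfp_scale_uv)
    return lfp, events


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

def _gain_at(times: np.ndarray, spec: UnitSpec,
             event_peaks: np.ndarray) -> np.ndarray:
    """Multiplicative rate gain at the given times (piecewise constant)."""
    gains = np.ones_like(times)
    if spec.unit_class == "none" or event_peaks.size == 0:
        return gains
    a_ms, b_ms = CLASS_WINDOWS[spec.unit_class]
    a, b = a_ms / 1000.0, b_ms / 1000.0
    # a spike at t is inside the window of event p iff p in (t - b, t - a]
    lo = np.searchsorted(event_peaks, times - b, side="left")
    hi = np.searchsorted(event_peaks, times - a, side="right")
    gains[hi > lo] = spec.gain
    return gains


def _thin_inhomogeneous(spec: UnitSpec, event_peaks: np.ndarray,
                        span: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    lam_max = spec.baseline_rate_hz * max(spec.gain, 1.0)
    lo, hi = span
    n_cand = rng.poisson(lam_max * (hi - lo))
    cand = np.sort(rng.uniform(lo, hi, n_cand))
    lam = spec.baseline_rate_hz * _gain_at(cand, spec, event_peaks)
    keep = rng.uniform(0, lam_max, cand.size) < lam
    times = cand[keep]
    # absolute refractory period by deletion
    while times.size > 1:
        bad = np.flatnonzero(np.diff(times) < SPIKE_REFRACTORY_S) + 1
        if bad.size == 0:
            break
        times = np.delete(times, bad[np.r_[True, np.diff(bad) > 1]])
    return times


def gen_units(cfg: SimConfig, truth_events: EventSet,
              seed: int | None = None) -> list[SpikeTrain]:
    """Inhomogeneous Poisson trains for every configured unit."""
    span = (0.0, cfg.duration_s)
    base_seed = cfg.master_seed if seed is None else seed
    trains = []
    for i, spec in enumerate(cfg.units):
        rng = _rng(base_seed, "units", i)
        times = _thin_inhomogeneous(spec, truth_events.peak_times, span, rng)
        trains.append(SpikeTrain(f"u{i:03d}", f"ch{i % 8}", times, span))
    return trains


def apply_pair_injections(cfg: SimConfig, trains: list[SpikeTrain],
                          seed: int | None = None) -> list[SpikeTrain]:
    """Correlate configured unit pairs by injecting shared jittered spikes.

    A hidden mother Poisson train at rate ``fraction * min(rate_i, rate_j)``
    is copied into both units with independent normal jitter; each unit's own
    train is thinned to keep its total baseline rate unchanged.
    """
    base_seed = cfg.master_seed if seed is None else seed
    trains = list(trains)
    for k, pair in enumerate(cfg.pairs):
        rng = _rng(base_seed, "pairs", k)
        ri = cfg.units[pair.unit_i].baseline_rate_hz
        rj = cfg.units[pair.unit_j].baseline_rate_hz
        shared_rate = pair.injection_fraction * min(ri, rj)
        lo, hi = trains[pair.unit_i].span
        n_shared = rng.poisson(shared_rate * (hi - lo))
        mother = np.sort(rng.uniform(lo, hi, n_shared))
        for idx, r_own in ((pair.unit_i, ri), (pair.unit_j, rj)):
            tr = trains[idx]
            keep = rng.uniform(size=tr.times.size) < (r_own - shared_rate) / r_own
            jit = rng.normal(0.0, pair.injection_jitter_ms / 1000.0, mother.size)
            merged = np.unique(np.concatenate([tr.times[keep],
                                               np.clip(mother + jit, lo, hi)]))
            merged = merged[(merged >= lo) & (merged <= hi)]
            trains[idx] = SpikeTrain(tr.unit_id, tr.channel_id, merged, tr.span)
    return trains


def gen_correlated_pair(base_rate_hz: float, injection_fraction: float,
                        jitter_ms: float, span: tuple[float, float],
                        seed: int = 0,
                        unit_ids: tuple[str, str] = ("pairA", "pairB")
                        ) -> tuple[SpikeTrain, SpikeTrain]:
    """Two equal-rate Poisson trains sharing a jittered fraction of spikes."""
    if not 0.0 <= injection_fraction <= 1.0:
        raise ValueError("injection_fraction must be in [0, 1]")
    rng = _rng(seed, "pairs")
    lo, hi = span
    t_len = hi - lo
    mother = np.sort(rng.uniform(lo, hi, rng.poisson(
        injection_fraction * base_rate_hz * t_len)))
    out = []
    for uid in unit_ids:
        own = rng.uniform(lo, hi, rng.poisson(
            (1.0 - injection_fraction) * base_rate_hz * t_len))
        jit = rng.normal(0.0, jitter_ms / 1000.0, mother.size)
        times = np.unique(np.concatenate([own, np.clip(mother + jit, lo, hi)]))
        out.append(SpikeTrain(uid, "chX", times, span))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def gen_dataset(cfg: SimConfig, outdir, force: bool = False) -> dict[str, Path]:
    """Generate and write a full labelled dataset; bit-reproducible per seed.

    Writes ``lfp.csv``, ``spikes.csv``, ``events_truth.csv``,
    ``classes_truth.csv`` and ``config.json`` into *outdir* and returns the
    path of each artifact.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty; "
                              "pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)
    lfp, truth_events = gen_lfp(cfg)
    trains = gen_units(cfg, truth_events)
    trains = apply_pair_injections(cfg, trains)

    paths = {
        "lfp": outdir / "lfp.csv",
        "spikes": outdir / "spikes.csv",
        "events_truth": outdir / "events_truth.csv",
        "classes_truth": outdir / "classes_truth.csv",
        "config": outdir / "config.json",
    }
    write_lfp(lfp, paths["lfp"])
    write_spike_trains(trains, paths["spikes"])
    write_events(truth_events, paths["events_truth"])
    with open(paths["classes_truth"], "w", encoding="utf-8") as fh:
        fh.write("unit_id,unit_class,gain,baseline_rate_hz\n")
        for tr, spec in zip(trains, cfg.units):
            fh.write(f"{tr.unit_id},{spec.unit_class},{spec.gain:.6f},"
                     f"{spec.baseline_rate_hz:.6f}\n")
    with open(paths["config"], "w", encoding="utf-8") as fh:
        fh.write(cfg.to_json())
        fh.write("\n")
    return paths
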