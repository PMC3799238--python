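"""Shared fixtures: small builders plus one session-scoped recovery dataset."""

from __future__ import annotations

import numpy as np
import pytest

from iedflow import (EventSet, RunConfig, SimConfig, SpikeTrain,
                     default_unit_specs, detect_ids, gen_lfp, gen_units,
                     run_pipeline)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230918)


def make_train(times, unit_id="u", channel_id="c", span=None) -> SpikeTrain:
    times = np.asarray(times, dtype=float)
    if span is None:
        hi = float(times.max()) + 1.0 if times.size else 1.0
        span = (0.0, hi)
    return SpikeTrain(unit_id, channel_id, times, span)


def make_events(peaks, halfwidth_s=0.1, channel="c") -> EventSet:
    peaks = np.asarray(peaks, dtype=float)
    return EventSet(
        peak_times=peaks, onsets=peaks - halfwidth_s,
        offsets=peaks + halfwidth_s, amplitudes=np.ones(peaks.size),
        channel_ids=np.array([channel] * peaks.size, dtype=object),
        source="imported",
    )


def poisson_train(rate_hz, span, rng, unit_id="u", channel_id="c") -> SpikeTrain:
    lo, hi = span
    n = rng.poisson(rate_hz * (hi - lo))
    times = np.unique(rng.uniform(lo, hi, n))
    return SpikeTrain(unit_id, channel_id, times, span)


@pytest.fixture(scope="session")
def recovery_dataset():
    """40-unit dataset (12/16/5/7 modulated classes) with ~150 true events.

    Shared by the detector-recovery and class-recovery tests; expensive, so
    built once per session.
    """
    units = default_unit_specs(40, seed=0)
    cfg = SimConfig(duration_s=2145.0, event_rate_hz=0.07, units=units,
                    master_seed=20230918)
    lfp, truth = gen_lfp(cfg)
    trains = gen_units(cfg, truth)
    detected = detect_ids(lfp)
    return cfg, lfp, truth, trains, detected


@pytest.fixture(scope="session")
def recovery_report(recovery_dataset):
    """Full pipeline run on the recovery dataset (spectral/synchrony off)."""
    cfg, *_ = recovery_dataset
    run_cfg = RunConfig(sim=cfg, master_seed=cfg.master_seed,
                        run_spectral=False, sync_pairs="none")
    return run_pipeline(run_cfg)
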