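"""End-to-end orchestration: simulate/load -> detect -> rates -> spectral ->
synchrony, with a consolidated, reproducible report.

Every stage persists its artifacts through :mod:`iedflow.io_formats` so each
stage can be re-run and inspected in isolation.  All stochastic stages draw
from the master seed; two runs with the same config and seed produce
identical reports (timestamps excluded, of which there are none).

No multiple-testing correction is applied across pairs by default (the
per-pair levels are stated in the report); a Bonferroni option exists.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import event_detection, io_formats, spectral, synchrony, unit_rates
from .io_formats import EventSet, LfpSignal, SpikeTrain, logger
from .synthetic_data import SimConfig, apply_pair_injections, gen_lfp, gen_units

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs plus per-stage parameter blocks (defaults = study values)."""

    sim: SimConfig | None = None
    lfp_path: str | None = None
    spikes_path: str | None = None
    events_path: str | None = None
    channel: str | None = None
    use_provided_events: bool = False

    detector: event_detection.DetectorParams = field(
        default_factory=event_detection.DetectorParams)
    windows: unit_rates.PeriEventWindows = field(
        default_factory=unit_rates.PeriEventWindows)
    min_events: int = 10
    rate_sigma_ms: float = 20.0
    psth_bin_ms: float = 10.0

    run_spectral: bool = True
    morlet_fmin_hz: float = 20.0
    morlet_fmax_hz: float = 300.0
    morlet_step_hz: float = 2.0
    nco: float = 5.0
    hfo_band_hz: tuple[float, float] = (40.0, 120.0)

    sync_pairs: str | list[tuple[str, str]] = "configured"
    ccg_jitter_sd_ms: float = 50.0
    n_surrogates: int = 1000
    ccg_coverage: float = 0.99
    coincidence_window_ms: float = 5.0
    dither_halfwidth_ms: float = 5.0
    coincidence_p: float = 0.001
    bonferroni_pairs: bool = False

    master_seed: int = 0
    outdir: str | None = None
    force: bool = False


@dataclass
class RunReport:
    seed: int
    config_echo: dict
    n_units: int
    n_units_qc: int
    n_events: int
    event_rate: dict
    modulation: pd.DataFrame
    proportions: dict
    group_tests: dict
    hfo: dict | None
    ks: dict | None
    synchrony: pd.DataFrame
    fraction_ccg_significant: float | None
    fraction_coincidence_significant: float | None
    version: str = __version__

    def to_results(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "seed", "n_units", "n_units_qc", "n_events", "event_rate",
            "proportions", "group_tests", "hfo", "ks",
            "fraction_ccg_significant", "fraction_coincidence_significant",
            "version")}
        d["config"] = self.config_echo
        d["modulation"] = self.modulation
        d["synchrony"] = self.synchrony
        return d


def summarize_proportions(mods: list[unit_rates.ModulationResult]) -> dict:
    """Per-class unit proportions with exact (Clopper-Pearson) 95% CIs."""
    if not mods:
        raise ValueError("need >= 1 classified unit")
    n = len(mods)
    flags = {
        "id_increase": [m.class_id == "increase" for m in mods],
        "post_decrease": [m.class_post == "decrease" for m in mods],
        "pre_increase": [m.class_pre == "increase" for m in mods],
        "pre_decrease": [m.class_pre == "decrease" for m in mods],
    }
    out = {}
    for name, hits in flags.items():
        k = int(np.sum(hits))
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        out[name] = {"count": k, "n": n, "proportion": k / n,
                     "ci95_low": float(lo), "ci95_high": float(hi)}
    return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("inputs")
def _load_inputs(cfg: RunConfig, outdir: Path | None
                 ) -> tuple[LfpSignal, list[SpikeTrain], EventSet | None]:
    if cfg.sim is not None:
        lfp, truth = gen_lfp(cfg.sim)
        trains = apply_pair_injections(cfg.sim, gen_units(cfg.sim, truth))
        if outdir is not None:
            io_formats.write_lfp(lfp, outdir / "lfp.csv")
            io_formats.write_spike_trains(trains, outdir / "spikes.csv")
            io_formats.write_events(truth, outdir / "events_truth.csv")
        return lfp, trains, (truth if cfg.use_provided_events else None)
    if cfg.lfp_path is None or cfg.spikes_path is None:
        raise ValueError("need either a simulation config or input paths")
    lfp = io_formats.read_lfp(cfg.lfp_path, cfg.channel)
    trains = io_formats.read_spike_trains(cfg.spikes_path)
    events = (io_formats.read_events(cfg.events_path)
              if cfg.use_provided_events and cfg.events_path else None)
    return lfp, trains, events


@_stage("quality_filter")
def _qc(trains: list[SpikeTrain]) -> list[SpikeTrain]:
    kept = [t for t in trains if unit_rates.passes_quality(t)]
    if not kept:
        raise ValueError(
            "no unit passes the ISI quality filter (< 0.5% intervals "
            "below 1 ms); check spike sorting / input units")
    return kept


@_stage("event_detection")
def _detect(cfg: RunConfig, lfp: LfpSignal, provided: EventSet | None
            ) -> EventSet:
    if provided is not None:
        return event_detection.align_events(provided, lfp)
    return event_detection.detect_ids(lfp, cfg.detector)


def _resolve_pairs(cfg: RunConfig, trains: list[SpikeTrain]
                   ) -> list[tuple[str, str]]:
    ids = [t.unit_id for t in trains]
    if cfg.sync_pairs == "none":
        return []
    if cfg.sync_pairs == "all":
        return [(ids[i], ids[j]) for i in range(len(ids))
                for j in range(i + 1, len(ids))]
    if cfg.sync_pairs == "configured":
        if cfg.sim is None:
            return []
        out = []
        for p in cfg.sim.pairs:
            ua, ub = f"u{p.unit_i:03d}", f"u{p.unit_j:03d}"
            if ua in ids and ub in ids:
                out.append((ua, ub))
        return out
    return list(cfg.sync_pairs)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages in order; any failure aborts naming the stage."""
    outdir = None
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        if outdir.exists() and any(outdir.iterdir()) and not cfg.force:
            raise PipelineError(f"output dir {outdir} exists; use force")
        outdir.mkdir(parents=True, exist_ok=True)

    lfp, trains, provided = _load_inputs(cfg, outdir)
    all_units = len(trains)
    trains = _qc(trains)
    by_id = {t.unit_id: t for t in trains}

    events = _detect(cfg, lfp, provided)
    if outdir is not None:
        io_formats.write_events(events, outdir / "events.csv")
    span = (lfp.t0, lfp.t0 + lfp.duration)
    rate = event_detection.event_rate(events, span)

    # peri-event firing modulation
    mods: list[unit_rates.ModulationResult] = []
    psth_rows = []
    for tr in trains:
        raster = unit_rates.peri_event_raster(tr, events,
                                              cfg.windows.raster_halfwidth)
        if raster.n_events < cfg.min_events:
            logger.info("unit %s skipped: %d usable events", tr.unit_id,
                        raster.n_events)
            continue
        centers, psth_rate = unit_rates.psth(raster, cfg.psth_bin_ms)
        psth_rows.append(pd.DataFrame({"unit_id": tr.unit_id,
                                       "time_ms": centers,
                                       "rate_hz": psth_rate}))
        mods.append(unit_rates.classify_modulation(
            raster, cfg.windows, cfg.min_events))
    if not mods:
        raise PipelineError("stage 'modulation' failed: no unit had enough "
                            "usable events")
    mod_df = pd.DataFrame([{
        "unit_id": m.unit_id, "n_events": m.n_events,
        **{f"rate_{k}_hz": v for k, v in m.window_rates_hz.items()},
        "ratio_id": m.ratio_id, "ratio_pre": m.ratio_pre,
        "ratio_post": m.ratio_post, "class_id": m.class_id,
        "class_post": m.class_post, "class_pre": m.class_pre,
        "t_pre": m.t_pre, "p_pre": m.p_pre,
        "baseline_floored": m.baseline_floored} for m in mods])
    proportions = summarize_proportions(mods)

    group_tests = {}
    for name, cls_field, window, tail in (
            ("id_increase", "class_id", "id", "right"),
            ("post_decrease", "class_post", "post_id", "left")):
        grp = [m for m in mods
               if getattr(m, cls_field) != "none"]
        if len(grp) >= 2:
            t, p, df = unit_rates.group_rate_test(
                [m.window_rates_hz[window] for m in grp],
                [m.window_rates_hz["baseline"] for m in grp], tail)
            group_tests[name] = {"t": t, "p": p, "df": df}

    # spectral stage
    hfo = ks = None
    if cfg.run_spectral and len(events) >= 2:
        try:
            work = event_detection.preprocess_lfp(lfp)
            params = spectral.MorletParams(
                np.arange(cfg.morlet_fmin_hz,
                          cfg.morlet_fmax_hz + 1e-9, cfg.morlet_step_hz),
                cfg.nco)
            zmap = spectral.event_zscore_map(
                work, events, params,
                baseline_ms=cfg.windows.baseline,
                halfwidth_ms=cfg.windows.raster_halfwidth)
            score = spectral.preid_hfo_score(zmap, cfg.hfo_band_hz,
                                             cfg.windows.pre_id)
            hfo = dataclasses.asdict(score)
            coeffs = spectral.baseline_coefficient_sample(
                work, events, float(np.mean(cfg.hfo_band_hz)), params,
                cfg.windows.baseline)
            ksr = spectral.ks_normality(coeffs)
            ks = dataclasses.asdict(ksr)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'spectral' failed: {exc}") from exc

    # synchrony stage
    sync_rows = []
    pairs_todo = _resolve_pairs(cfg, trains)
    n_tests = max(1, len(pairs_todo))
    for ua, ub in pairs_todo:
        a, b = by_id[ua], by_id[ub]
        if synchrony.skip_ineligible(a, b):
            continue
        rng = synchrony.pair_rng(cfg.master_seed, ua, ub)
        try:
            coverage = cfg.ccg_coverage
            p_coin = cfg.coincidence_p
            if cfg.bonferroni_pairs:
                coverage = 1.0 - (1.0 - coverage) / n_tests
                p_coin = p_coin / n_tests
            ccg = synchrony.cross_correlogram(a, b)
            band = synchrony.jitter_band(a, b, cfg.ccg_jitter_sd_ms,
                                         cfg.n_surrogates, coverage, rng)
            ccg_res = synchrony.ccg_significant(ccg, band)
            series = synchrony.coincidence_series(
                a, b, events, cfg.coincidence_window_ms)
            thr = synchrony.dither_threshold(
                a, b, events, cfg.dither_halfwidth_ms, cfg.n_surrogates,
                p_coin, rng, cfg.coincidence_window_ms)
            coin_res = synchrony.coincidence_significant(series, thr,
                                                         cfg.windows)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'synchrony' failed: {exc}") from exc
        sync_rows.append({
            "unit_a": ua, "unit_b": ub,
            "ccg_significant": ccg_res.significant,
            "ccg_peak_within_25ms": ccg_res.peak_within_25ms,
            "ccg_significant_lags_ms": ";".join(
                f"{v:g}" for v in ccg_res.significant_lags_ms),
            "coincidence_significant": coin_res.significant,
            "coincidence_significant_bins_ms": ";".join(
                f"{v:g}" for v in coin_res.significant_bins_ms),
        })
    sync_df = pd.DataFrame(sync_rows, columns=[
        "unit_a", "unit_b", "ccg_significant", "ccg_peak_within_25ms",
        "ccg_significant_lags_ms", "coincidence_significant",
        "coincidence_significant_bins_ms"])

    report = RunReport(
        seed=cfg.master_seed,
        config_echo=_config_echo(cfg),
        n_units=all_units, n_units_qc=len(trains), n_events=len(events),
        event_rate=dataclasses.asdict(rate),
        modulation=mod_df, proportions=proportions, group_tests=group_tests,
        hfo=hfo, ks=ks, synchrony=sync_df,
        fraction_ccg_significant=(
            float(sync_df["ccg_significant"].mean()) if len(sync_df) else None),
        fraction_coincidence_significant=(
            float(sync_df["coincidence_significant"].mean())
            if len(sync_df) else None),
    )
    if outdir is not None:
        psth_df = (pd.concat(psth_rows, ignore_index=True)
                   if psth_rows else pd.DataFrame())
        psth_df.to_csv(outdir / "psth.csv", index=False,
                       float_format="%.6f")
        io_formats.write_report(report.to_results(), outdir / "report.json")
    return report


def _config_echo(cfg: RunConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    return io_formats._jsonable(echo)
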