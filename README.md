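# iedflow

Analysis pipeline for single-unit firing and LFP dynamics around
**interictal epileptiform discharges (IDs)** — the transient pathological
events seen between seizures in epileptic tissue, each a sharp 20–100 ms
component usually followed by a 200–500 ms slow wave.

The package is written for electrophysiologists working with human or animal
microelectrode recordings (simultaneous LFP + sorted spike trains) who want
a tested, scriptable version of the classical peri-event analysis chain:

1. **Event detection** (`iedflow.event_detection`) — threshold-based ID
   detector on the detrended LFP: amplitude > `amp_k`·σ̂ (robust
   median/MAD scale), slope criterion on a 50-ms increment, event extent
   within 20–100 ms, both polarities, 300-ms refractory merging; events
   aligned on the sharpest peak.
2. **Unit rates** (`iedflow.unit_rates`) — ISI quality filter (< 0.5 %
   intervals within 1 ms), Gaussian-kernel instantaneous rate (σ = 20 ms,
   1-ms steps), peri-event rasters (±1 s) and 10-ms PSTHs, and per-unit
   modulation classes over four windows relative to the event peak:
   baseline [−600, −300) ms, pre-ID [−300, −50) ms, ID [−50, 50) ms,
   post-ID [50, 400) ms.  A unit is an *ID-increase* if
   rate(ID)/rate(baseline) ≥ 2, a *post-decrease* if
   rate(post)/rate(baseline) ≤ 0.5, and pre-ID changes are assessed with a
   per-unit paired t-test across events (α = 0.05).  Group-level one-sample
   t-tests on per-unit differences (df = n−1) mirror the per-class summary
   statistics.
3. **Spectral** (`iedflow.spectral`) — complex Morlet transform with
   σ(f) = nco/(6f), nco = 5, over 20–300 Hz; power Z-scored per frequency
   against the pooled baseline windows and averaged across events; |Z| > 3.09
   (one-sided normal tail 0.001) masks significant time–frequency cells; a
   40–120 Hz pre-ID peak score; Lilliefors/KS normality check of the wavelet
   coefficients.
4. **Synchrony** (`iedflow.synchrony`) — two surrogate tests per unit pair
   (> 100 spikes each): (a) cross-correlogram on 1-ms bins over ±100 ms
   against a 99 % band from 1000 surrogates with N(0, 50 ms) spike jitter,
   significant if any bin with |lag| ∈ [1.5, 30] ms exceeds the band
   (±25 ms peak location reported separately); (b) 5-ms-window spike
   coincidences per 10-ms peri-event bin against per-bin 99.9 % thresholds
   from 1000 surrogates with uniform ±5 ms dither.
5. **Synthetic data** (`iedflow.synthetic_data`) — ground-truth-labelled
   recordings: 1/f background with embedded ID templates (Poisson event
   times with a 2-s refractory, default 0.07 Hz), optional pre-ID 40–120 Hz
   burst, and inhomogeneous-Poisson units (baseline 2–7 Hz) whose rate is
   gated by class-specific gains in the windows above; correlated pairs via
   common-spike injection with millisecond jitter.
6. **Pipeline + CLI** (`iedflow.pipeline`, `iedflow` console script) —
   simulate → detect → rates → spectral → synchrony in one seeded,
   bit-reproducible run with CSV/JSON artifacts.

## Worked example

```python
from iedflow import (SimConfig, PreIdBurst, RunConfig, run_pipeline,
                     default_unit_specs)
from iedflow.synthetic_data import PairSpec

sim = SimConfig(duration_s=600.0, event_rate_hz=0.07,
                units=default_unit_specs(20, seed=0),
                pairs=[PairSpec(0, 1, 0.15, 3.0)],
                preid_burst=PreIdBurst(enabled=True), master_seed=7)
report = run_pipeline(RunConfig(sim=sim, master_seed=7))
```

This simulates 10 minutes of LFP with discharges at 0.07 Hz, 20 units in the
default class mix, one correlated pair, and a 90-Hz pre-ID oscillation, then
runs the full chain.  The run prints/reports:

```
events detected: 38 | event rate: 0.063 Hz
units passing QC: 20 of 20
  id_increase: 6/20 = 0.30 (95% CI 0.12-0.54)
  post_decrease: 7/20 = 0.35 (95% CI 0.15-0.59)
  pre_increase: 3/20 = 0.15 (95% CI 0.03-0.38)
  pre_decrease: 5/20 = 0.25 (95% CI 0.09-0.49)
pre-event HFO: {'peak_z': 4.9, 'peak_freq_hz': 88.0, 'peak_time_ms': -178.0}
synchrony: u000/u001  ccg_significant=True  coincidence_significant=False
```

Reading: the detector recovered 38 of the ~40 embedded discharges (0.063 Hz
observed rate); the classified unit proportions match the generator's mix
(30 % ID-increase, 35 % post-decrease here); the pre-ID high-frequency score
finds the injected 90-Hz burst at Z ≈ 4.9 (well above the 3.09 cutoff); and
the correlated pair is flagged by the cross-correlogram test while
coincidence counts stay within the dither thresholds.

The same run is available from the shell:

```bash
iedflow run --seed 7 --out runs/demo
iedflow simulate --seed 3 --out data/sim
iedflow detect-ids --lfp data/sim/lfp.csv --out events.csv
```

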