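# Methods

This note documents the models, estimators and numerical choices behind
`iedflow`, and what the bundled synthetic-data generator does and does not
emulate.

## Signals and conventions

All times are seconds in double precision; window parameters are accepted in
milliseconds at interfaces and converted once.  Sample `i` of an LFP trace
sits at `t0 + i/fs` (0-based), and every time window is half-open `[a, b)`,
so boundary spikes are counted exactly once.  Delimited-text artifacts use
comma separation, `.` decimals, UTF-8 and a mandatory header; text round
trips are exact to 6 decimals, EDF round trips to one 16-bit quantization
step.

## Event detection

The detector targets interictal discharges: transients with a pointed,
large-amplitude 20–100 ms component, often followed by a slow wave.  The
trace is decimated to 1 kHz (4th-order Butterworth anti-alias low-pass at
300 Hz, zero-phase) and detrended by subtracting a centred 2-s moving
median, which removes drift without rounding the sharp component the way a
band-pass would.  Background statistics are robust: centre = median,
scale σ̂ = 1.4826·MAD, so the discharges themselves cannot inflate the
threshold.

A candidate is a contiguous run with |v − centre| > `amp_k`·σ̂ (default
`amp_k` = 6, both polarities).  Three refinements make the criteria usable
in practice:

* **Slope** is the signal increment over a `slope_step_ms` = 50 ms step of a
  5-ms-Gaussian-smoothed trace, thresholded at `slope_k` = 5 robust SDs of
  that increment trace.  A per-sample first difference cannot work here: at
  1 kHz the sample-to-sample change of a 60-ms-wide transient (~0.2 σ̂) is
  far below the first-difference noise of either white or 1/f background.
  The 50-ms step matches the rise time of the admissible sharp components,
  and measuring it on the smoothed trace makes the threshold insensitive to
  the noise colour (white-noise increments collapse under smoothing; 1/f
  increments, dominated by low frequencies, do not change).
* **Duration** (and the event's onset/offset) is the extent of the
  contiguous region around the peak where the smoothed rectified trace
  exceeds a lower edge threshold `edge_k`·σ̂ (default 2.5), and must fall in
  [20, 100] ms.  Measuring duration at the detection threshold itself would
  accept blunt high-amplitude waves whose tip spends 20–100 ms above it; at
  the edge level a 60-ms-FWHM sharp component of amplitude 8 σ̂ measures
  ~78 ms while a 150-ms half-sine of the same amplitude measures ~120 ms and
  is rejected.  `edge_k` = 2.5 leaves ~20 ms of margin on both sides; at 2.0
  background excursions pushed ~3 % of true events past the 100-ms cap.
* **Peak localization** uses the 5-ms-Gaussian-smoothed rectified trace:
  the template apex is locally flat, so the raw argmax scatters by >10 ms at
  amplitude 8 σ̂ while the smoothed argmax stays within a few ms.

Candidates closer than `refractory_ms` = 300 ms are merged keeping the
larger (smoothed) peak, so a spike-and-slow-wave complex yields one event.
Detection is invariant to constant offsets and equivariant under sign flips;
raising `amp_k` can only remove events.  Event-rate summaries report the
mean (count/duration) plus SD/min/max over non-overlapping 60-s epochs; a
span shorter than one epoch reports the dispersion as missing.

## Unit rates and modulation classes

Units enter the analysis only if fewer than 0.5 % of their inter-spike
intervals fall below 1 ms.  The instantaneous rate is the sum of unit-area
Gaussian kernels (σ = 20 ms, sampled each 1 ms, grid padded by 5σ), so the
trace integral equals the spike count to float precision; the discrete
kernel is renormalized to unit area on the grid.

Peri-event rasters collect latencies in [−1000, 1000) ms; events whose
window does not fit in the recording span are dropped and counted.  PSTHs
use 10-ms bins (counts / (n_events · bin width)).

Window rates use **raw counts**, not the smoothed trace: a 20-ms kernel
would leak appreciable mass across the 100-ms ID window.  Classes:

* ID window: *increase* iff rate(ID)/rate(baseline) ≥ 2;
* post-ID window: *decrease* iff the ratio ≤ 0.5;
* pre-ID window: per-unit paired two-sided t-test across events
  (per-event pre-ID rate vs per-event baseline rate) at α = 0.05, direction
  from the sign of the mean difference.  This is an interpretation: the
  across-event variance structure exposed by the rasters is the natural
  error model for a per-unit test, but other choices (e.g. a ratio cutoff)
  are defensible.  Both the ratios and the test are reported so users can
  apply either criterion.

A silent baseline gets a rate floor of ε = 0.1 Hz added to numerator and
denominator of the ratios (flagged); ε is small against the ≥1.4 Hz rates
where the ratios matter.  Group-level tests are one-sample t-tests on
per-unit (window − baseline) differences with df = n−1, matching the
degrees of freedom such summaries print; a zero-variance difference vector
is decided by its sign and flagged.

## Morlet time–frequency maps

The wavelet at frequency f is a complex sinusoid under a Gaussian envelope
of SD σ(f) = nco/(6f), nco = 5, truncated at ±5σ.  The kernel is
normalized to **unit area**, so a pure tone of amplitude A gives a flat
response |W| = A/2 at the tone frequency for every f and the discrete
argmax over a 2-Hz grid is unbiased; with the more common √f (L2)
normalization the f^(−1/2) envelope biases the argmax a full grid step low
at 80 Hz.  The choice is free of consequence downstream: any per-frequency
prefactor cancels identically in the baseline Z-scores.  Power is |W|²;
samples within half a kernel of either edge are flagged invalid and never
enter baselines, masks or scores.

Baseline correction pools, per frequency, the power over all events'
baseline windows ([−600, −300) ms before the peak), subtracts the pooled
mean and scales by 1/SD; the normalized per-event maps are then averaged.
Pooling (rather than per-event normalization) stabilizes the SD estimate.
Note that averaging N normalized maps shrinks the null fluctuation to
~1/√N while a consistent power shift keeps its Z value, so the |Z| > 3.09
mask (one-sided normal tail 0.001) is conservative on averaged maps.  The
mask is two-sided on |Z| by default; a one-sided option exists because the
stated pairing of 3.09 with P < 0.001 is one-sided.

The KS normality check uses Lilliefors critical values (mean and SD are
estimated from the sample) and is applied to the real part of the wavelet
coefficients — coefficients of a Gaussian background are Gaussian, their
squared modulus is not.

## Spike synchrony

Pairs need > 100 spikes per train.  Cross-correlograms count ordered lags
t_b − t_a in 1-ms half-open bins over ±100 ms; the implementation is
vectorized (sorted-array window search) and is tested to agree exactly with
the O(n²) double loop.  The jitter null adds independent N(0, 50 ms)
offsets to **every spike of both trains** (the symmetric null; a one-train
mode is available), recomputes the correlogram 1000 times and takes per-bin
empirical [0.5 %, 99.5 %] quantiles (linear interpolation between order
statistics).  A pair is significant if any bin with |lag| ∈ [1.5, 30] ms
exceeds the upper bound; whether a significant bin lies within ±25 ms of
the origin is reported as a separate flag rather than used as the
criterion.

A coincidence is an ordered cross pair with |t_b − t_a| ≤ 2.5 ms (5-ms
total window) inside the same event's raster, assigned to the 10-ms
peri-event bin of the earlier spike — a pure pair count with an exhaustive
oracle.  (A greedy at-most-one-match variant is available.)  The dither
null displaces every spike independently by U(−5, +5) ms, clipping
latencies at the raster edge minus a vanishing offset so per-train counts
are preserved, and takes the per-bin 99.9 % quantile of 1000 surrogate
counts as the threshold.

**Calibration caveats** (measured by the test suite on independent Poisson
pairs):

* the jitter band's true per-bin coverage is ~99.3 %, not 99.0 %:
  empirical quantile bands on integer counts are conservative because of
  ties at the discrete quantiles (the same value is obtained with ideal
  i.i.d. Poisson draws, so this is not a property of the surrogate
  coupling);
* the dither threshold's per-bin exceedance is ≈ 0 rather than the nominal
  0.001: a ±5 ms dither retains an existing 5-ms coincidence with
  probability ~0.44, so surrogates almost always reproduce the observed
  count and the threshold sits at or above it.  The test therefore controls
  false positives very conservatively, and detections require a genuine
  excess of near-coincidences over what rate-preserving dithering can
  produce.

Per-pair surrogate RNGs derive from a master seed plus a CRC32 hash of the
unit ids, so results are independent of analysis order.  No multiple-testing
correction is applied across pairs by default (the per-pair levels are
reported); a Bonferroni option exists.

## Synthetic data

The generator provides labelled ground truth with the statistical structure
the analysis assumes:

* **LFP**: spectrally synthesized 1/f^α Gaussian background (α = 1),
  robust SD normalized to 25 µV.  Discharge templates are a sharp Gaussian
  lobe (FWHM = `id_sharp_width_ms`, default 60 ms, admissible 20–100 ms)
  with a biphasic dip, followed by a slow half-wave (default 350 ms,
  admissible 200–500 ms); the template peak is `id_amp_snr` = 8 background
  robust SDs.  Event times are a hard-core renewal process (exponential
  gaps plus a 2-s refractory, compensated so the mean rate equals
  `event_rate_hz`, default 0.07 Hz — the scale at which such discharges
  occur in chronic recordings).  The optional pre-event burst is a
  Hann-windowed sinusoid (default 90 Hz) in [−300, −50) ms; its default
  amplitude (0.55 robust SD) is calibrated so the averaged peri-event
  Z-map peaks at Z ≈ 5–8, the scale reported for pre-discharge 40–120 Hz
  oscillations.
* **Units**: inhomogeneous Poisson trains sampled by thinning; each unit's
  rate is its baseline (drawn once from U(2, 7) Hz) multiplied by a class
  gain inside its class window around every true event.  Gating is
  piecewise-constant so per-window rates are analytically known for
  recovery tests.  Defaults: 30 % ID-increase (gain 3), 40 % post-decrease
  (gain 0.4), 12 %/18 % pre-increase/decrease (gains 2.5/0.3).  A 1.5-ms
  absolute refractory period is enforced by deletion, so generated units
  pass the ISI filter by construction.
* **Pairs**: shared spikes copied from a hidden mother Poisson train with
  independent N(0, jitter) offsets (default 3 ms), own trains thinned to
  keep total rates at baseline; the correlogram peak has width ≈ √2·jitter.

All randomness flows from `master_seed` through named substreams (lfp,
units, pairs), so components regenerate independently and datasets are
byte-reproducible.

What the generator does **not** emulate: sporadic super-Poisson clustering
of discharges, waveform variability across events (amplitude and width are
fixed per dataset), non-Poisson spiking (bursting, refractory-driven
regularity beyond 1.5 ms), rate co-modulation between units beyond the
injected pairs, volume conduction across channels, and artifacts.  Passing
the recovery tests therefore shows the estimators are correct under the
assumed model, not that the detector thresholds are optimal for any
particular recording system.

## Problem sizes in the test suite

The bundled tests run the recovery analysis on a 40-unit dataset
(12 ID-increase, 16 post-decrease, 5 pre-increase, 7 pre-decrease) with
~150 true events over ~36 minutes of 1-kHz LFP, and the surrogate
calibrations on 200 independent 5-Hz/300-s Poisson pairs with 1000
surrogates each — sizes chosen to keep the whole suite in the low minutes
while leaving the statistical checks well-powered.

## Known limitations

* The detector's thresholds (`amp_k`, `slope_k`, `edge_k`) are engineering
  defaults tuned for SNR ≈ 8 transients on 1/f background; recordings with
  different noise floors need re-tuning (all exposed in `DetectorParams`).
* The admissible-duration filter measures extent at the edge threshold, so
  the mapping from a component's FWHM to its measured duration depends on
  its amplitude; near-boundary widths (~100 ms FWHM) can be rejected.
* Morlet edge invalidation discards half a kernel at each end; at 20 Hz
  that is ~0.2 s per edge, so very short traces lose a large valid
  fraction.
* The dither coincidence test is strongly conservative (see above); absence
  of flagged pairs is weak evidence of absence.
* EDF output is 16-bit with a single channel per file and integer sampling
  rates; traces are zero-padded to whole seconds.
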