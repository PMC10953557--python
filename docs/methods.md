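# Methods

This note documents the models, estimators, and numerical choices
behind `meascreen`, and what the synthetic-data tests do and do not
establish about real recordings.

## Recording model and detection chain

Raw data are per-electrode voltage traces in microvolts, 48 wells × 16
electrodes sampled at 12.5 kHz (the plate geometry and rate of common
multi-well MEA systems).  Detection mirrors a standard acquisition
chain:

1. **Band-pass:** 1-pole Butterworth, 250–3000 Hz.  The filter is
   applied forward-backward (zero phase) so detected timestamps carry
   no phase skew; the single-pass design has −3 dB gain at the band
   edges, and the zero-phase application squares the magnitude
   response.  Vendors do not publish their phase handling; zero-phase
   is this package's choice and is visible in the white-noise spectrum
   test (`|H|⁴`).
2. **Adaptive threshold:** ±5.5 σ, where σ is tracked as
   `median(|x|)/0.6745` over 10 s windows (piecewise constant).  The
   median estimator is insensitive to the sparse large deflections that
   spikes superimpose on the noise floor (≤ 5% bias at ~5 Hz of 10 σ
   events).  Whether commercial systems adapt per window or per sample
   is unpublished; the window length is a config parameter so
   sensitivity can be probed.
3. **Event extraction:** an event is the first suprathreshold sample of
   a crossing (either sign); one event per 1 ms dead time; cutouts
   1 ms pre / 2 ms post, zero-padded at trace edges.

At 5.5 σ the Gaussian tail predicts ~2·Φc(5.5)·fs ≈ 5×10⁻⁴ false
crossings per second per electrode; the measured rate on filtered noise
is lower still (correlated samples cluster within the dead time).  At a
spike-to-noise amplitude ratio of 8 the chain recovers ≥ 95% of ground
truth spikes at ≥ 95% precision (±0.5 ms).

## Activity and synchrony metrics

* **Active electrode:** ≥ 1 spike per minute, boundary inclusive.
  **Active well:** ≥ 5 active electrodes (the stricter of the two
  plausible readings of the conventional "> 4" rule; configurable).
  Undefined metrics (no active electrodes, < 2 ISIs) propagate as NaN
  with an exclusion flag, never as silent zeros.
* **MFR / WMFR:** per-electrode rate averaged over active electrodes,
  and total well spikes / (n_active × duration).  For equal-duration
  electrodes the two coincide — that identity is the documented
  contract, since vendor weighting conventions vary.
* **ISI CoV:** SD/mean of inter-spike intervals; 1 for Poisson firing,
  > 1 for bursty firing.
* **AUNCC:** for each electrode pair, both trains are binned at 5 ms
  and cross-correlated over lags ±100 ms.  The raw correlogram retains
  a chance-coincidence baseline (two independent 3 Hz trains coincide
  ~n_x·n_y/n_bins times per lag), so the implementation subtracts the
  homogeneous-firing chance level and counts only lags whose
  coincidence count exceeds chance by 3 Poisson SDs.  The pair score is
  the gated positive area, normalised by `sqrt(Σx²·Σy²)`, divided by
  the same quantity for the autocorrelogram of the higher-count train
  (ties broken by the larger auto area, which keeps the score invariant
  to electrode relabeling).  This normalisation pins the two anchors
  that make the score interpretable: a duplicated train scores exactly
  1, and independent Poisson trains score ~10⁻³ (the scale reported
  for asynchronous mono-cultures).  The well value is the pair mean,
  clipped to [0, 1].
* **Bursts:** maximal runs of ≥ 5 spikes with consecutive ISIs
  ≤ 100 ms (an ISI-threshold stand-in for unpublished vendor presets;
  all parameters in config).  **Network bursts:** electrode bursts
  padded by half a 100 ms alignment window; maximal regions where
  ≥ 25% of the well's active electrodes overlap, merged when touching.

## Synthetic plates

The generator is the package's stand-in for real recordings and defines
the study conditions for every test:

* **Background firing:** homogeneous Poisson per electrode.  Electrode
  rates are lognormal around the well mean with CV 0.59 — the
  dispersion implied by a mature plate firing 3.55 ± 2.10 Hz.  A
  configurable fraction of electrodes (default 0.97) is active.
* **Network bursts:** a shared well-level Poisson event process
  (default 0.063 events/s); at each event every electrode joins
  independently with probability `burst_participation` and emits
  Poisson(intra-rate × duration) spikes uniformly over the 1 s event.
  Participation is the monotone synchrony knob: AUNCC rises strictly
  over {0, 0.3, 0.6, 0.9}.  The shipped **DIV27 preset** (baseline
  1.0 Hz, participation 0.5, intra-burst 85 Hz) realises MFR ≈ 3.5 Hz
  and AUNCC ≈ 0.45–0.5 — a stable, synchronised mature co-culture.
* **Waveforms:** first derivative of a Gaussian (biphasic,
  charge-balanced), dominant peak 12 µV against 1.5 µV Gaussian noise
  (amplitude = 8 × noise SD, consistent with an ~8 µV signal scale;
  the noise floor is a free simulator choice since rigs differ), 10%
  amplitude jitter.  The spike timestamp convention is the first
  dominant lobe — what a threshold detector fires on.  Generated trains
  are post-processed to a 1 ms minimum ISI, matching the detector dead
  time.
* **Drug effects:** a bolus added at `t_add` scales the instantaneous
  rate as `r(t) = r0·(1 + (f−1)(1 − e^−(t−t_add)/τ))` — a
  single-exponential, diffusion-delayed onset.  Reductions are realised
  by thinning, increases by superposing a thinned dominating Poisson
  process.  Presets: lidocaine-like full block f = 0.1; TNF-α-like
  hyperexcitability f = 2.6 (DoS ≈ +0.45).
* **Stimulation sessions:** biphasic 800 mV / 600 µs-per-phase pulses
  every 4 s (10 repetitions) after a 45 s baseline.  Every electrode
  records a decaying artifact transient; only stimulated electrodes
  additionally receive a Gaussian-envelope oscillation burst (250 Hz
  centre, 1 s, default 10 µV) beginning 150 ms post-pulse.
* **Temperature ramps:** 37→42 °C at 2 °C/min with a 2 min hold;
  responder electrodes scale their rate by `gain^(T−37)`
  (inhomogeneous Poisson by thinning); non-responders are unchanged.

What the simulator does **not** model: biophysical neuron dynamics,
electrode drift and impedance changes, spike-waveform diversity and
overlap resolution, glia–neuron coupling, or well-edge effects.
Passing tests therefore certify the *analysis* chain (detection,
estimators, statistics) against a known generative process — they do
not certify biological realism of any particular plate.

## Screening statistics

* **Log spike count:** `log10(total spikes per well + 1)` over a fixed
  epoch.  The demo uses 300 s epochs (scaled down from hours-long
  screening recordings, with the onset τ scaled along) so a full
  72-well screen runs in seconds; a ~3 Hz × 16-electrode well then
  yields ~10⁴ spikes, i.e. log counts ≈ 4.2.
* **Stability:** three consecutive recordings are "stable" when all
  three pairwise two-sample proportion tests on AEY **and** a
  Kruskal–Wallis test across the per-well WMFR distributions give
  p > 0.05.  Identical recordings give p = 1 on all four tests.
* **Responsiveness:** chemical mode flags an electrode when any 30 s
  treatment bin reaches 2× max(mean baseline bin, 1 spike) — the
  1-spike floor keeps silent-baseline electrodes from trivially
  responding; temperature mode compares max bin against 2× max
  baseline bin.  Note the max-vs-max rule is strict: because the
  maximum of ~10 Poisson baseline bins exceeds the mean, a mere
  doubling of rate flags only a few percent of electrodes; reliable
  flagging needs ~4× or more (the binned-Poisson oracle and the
  pipeline agree on this).
* **Z′:** `1 − 3(σ_low + σ_high)/|μ_high − μ_low|` on per-well log
  counts, with a robust (median / 1.4826·MAD) variant.  The arms are
  named *high-signal* (vehicle) and *low-signal* (lidocaine) because
  positive/negative labels are used inconsistently across conventions.
  At 4 wells per arm the estimator is noticeably variable; with arms
  designed for a true Z′ of 0.56 the Monte-Carlo mean lands within
  ±0.1.
* **Hits:** |mean compound log count − median(reference)| > 3×MAD
  (two-sided, direction recorded).  The reference population is a
  config choice (same-plate baseline wells by default; vehicle- or
  TNF-α-referenced variants selectable) since conventions differ.  The
  rule is exactly translation invariant, and its false-positive rate on
  null compounds matches a direct Monte-Carlo of the rule.
* **Group battery:** Shapiro–Wilk per group at α = 0.05 gates a
  one-way ANOVA + Tukey HSD (all normal) versus Kruskal–Wallis +
  Dunn's post-hoc (otherwise; constant groups force this branch).
  Dunn's test is implemented in-package (pooled-rank z statistics with
  tie correction, Bonferroni-adjusted) as no dependency provides it.
  No correction is applied across compounds by default; a
  Benjamini–Hochberg option exists but is off.

## Evoked power (TPoB)

Traces are high-passed at 100 Hz (2nd-order Butterworth, zero-phase).
Each pulse defines a trial window of 3.5 s starting 50 ms after the
pulse (the blanked artifact interval); pseudo-trials replicate the
pulse spacing inside the pre-stimulation baseline.  Short-time spectra
use 0.25 s Hann windows at 50% overlap, PSD-scaled so that integrating
over frequency and averaging frames recovers the windowed variance
(Parseval, verified to 2%).  The band power per trial integrates
100–600 Hz, and

    TPoB = mean(trial band power) − mean(pseudo-trial band power),

converted to mV².  TPoB is exactly zero on identical windows, may be
negative on unstimulated electrodes (null-centered noise), is positive
on stimulated electrodes carrying an oscillation burst, and scales
quadratically with the injected amplitude.  Full-trial integration is
the documented default (whether a sub-window is used in other
implementations is unspecified); the 3.5 s window is the 4 s
inter-pulse interval minus the 0.5 s-scale artifact recovery, both
configurable.

## Pipeline and determinism

`run_screen` composes the stages (simulate → treat → epoch → metrics →
screening → TPoB) under one root seed.  Per-well substreams are derived
with `SeedSequence(entropy=seed, spawn_key=(well_index, stream))`, so
enlarging the plate never perturbs existing wells, and two runs with
the same seed and config write byte-identical tables.  A run started
from a precomputed spike table (timestamps serialised at 1 µs — finer
than one sample) reproduces the downstream results of the single-shot
run.  The report carries a provenance block (config hash, seed,
package version).

The demo screen uses a 72-well virtual plate: 15 compounds × 4 wells
plus vehicle, lidocaine, and TNF-α arms — the pooled replicate
structure of a multi-plate screen.  Ten compounds carry a designed
suppression (f = 0.1, the scale of a full sodium-channel block at a
saturating concentration) and five are designed nulls; the 3×MAD rule
recovers ≥ 9/10 with ≤ 1/5 false hits in the large majority of seeds.

## Known limitations

* The AUNCC normalisation is this package's own (vendor formulas are
  unpublished); it is anchored, documented, and tested, but absolute
  values are not comparable across software.
* Burst/network-burst parameters stand in for unpublished presets.
* No spike sorting: all metrics are electrode-level multi-unit.
* The chance-level used in AUNCC assumes locally homogeneous firing;
  strongly non-stationary recordings inflate pair scores.
* Screening epochs in the demo are minutes, not hours; rate statistics
  scale, but slow pharmacological onsets that straddle a 3 h recording
  are only represented through the scaled onset τ.
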