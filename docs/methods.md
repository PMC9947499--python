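# Methods

This note documents the models, estimators, numerical choices and
limitations behind `brainfog_eeg`, in the order data flows through the
pipeline.

## Synthetic study generator (`synth`)

### Paradigm schedules

The three cognitive paradigms are generated as trial schedules (trial
index, condition code, stimulus payload, onset):

* **Digit span** — 64 auditory sequences ordered by increasing length with
  per-length counts (10, 10, 5, 5, 5, 5, 9, 15) for lengths 3–10, digits
  drawn from 1–10, all sequences within a length block distinct. Onsets
  advance by a listening time proportional to sequence length plus a
  recall gap.
* **Task switching** — 150 trials, 75 with the letter/number pair in the
  top screen section (letter task-relevant) and 75 in the bottom (number
  relevant), randomized order, each trial carrying the correct-response
  flag (vowel / even number).
* **Face recognition** — 270 trials arranged as repeated 12-face blocks,
  each block a permutation of the face pool containing the 3 studied
  faces. 270 is not a whole number of blocks; the final block is truncated
  (configurable), so complete blocks carry exactly 3 known-face trials.

### Resting-state cascades

Avalanche structure is generated by the standard Galton–Watson branching
process with Poisson offspring: one seed event on a uniformly random
channel; each event in bin *t* spawns Poisson(σ) events in bin *t* + 1 on
uniformly random channels; the cascade ends at the first empty bin.
Poisson offspring is chosen because its mean is exactly the branching
parameter σ and its critical size distribution has the −3/2 exponent, so
both downstream estimators have closed-form targets:

* subcritical mean size E[s] = 1/(1 − σ), with total-progeny variance
  σ/(1 − σ)³ (used as the Monte-Carlo standard error in tests);
* at σ = 1, P(s) ∝ s^(−3/2) asymptotically.

A duration cap (default 100 bins) bounds supercritical runs; capped
cascades are flagged because their size is censored. Recovery experiments
at supercritical σ use a small cap (10–12 bins): the σ estimator reads
only the first two bins, so the cap does not touch its expectation, while
an uncapped run at σ = 1.1 would generate ~σ^100 ≈ 10⁴ events per
surviving cascade. Fixtures that render signal use a cap of 25 bins so
cascades fit inside a recording.

### Signal rendering

`render_resting_recording` places cascades sequentially on the 24-ms bin
grid with ≥ 2 empty guard bins between them (spare bins distributed
uniformly), over a background of per-channel 1/f-shaped Gaussian noise
(exponent 1 by default), z-scored to unit SD, with an optional 50 Hz line
tone. Each event becomes a deflection of random sign spanning one 8-ms
base bin — two samples at 250 Hz, one at 125 Hz — so a single detector
excursion corresponds to exactly one injected event after downsampling.

The event amplitude default is 20 background SDs. This is deliberately
far above the 2.7 SD detection threshold: the zero-phase 40 Hz low-pass
retains only ~55–60 % of a one-sample deflection's amplitude, and
detection thresholds are set in units of the *mixed* signal's SD, which
the events themselves inflate. At 20 SDs and ~3 cascades/s the injected
events dominate the variance enough that background Gaussian excursions
become rare (the mixture SD pushes the effective threshold to ≈ 4 noise
SDs), which is what makes end-to-end recovery of σ through the full
preprocessing chain possible. With weaker or sparser events the detector
output is progressively contaminated by background excursions, which
appear mostly as single-event avalanches and bias σ̂ downward — a real
phenomenon of threshold-crossing analysis on Gaussian backgrounds, not an
implementation artifact.

What the generator does *not* emulate: spatially correlated background
(channels are independent), physiological artifacts (eye blinks, muscle;
a square-pulse injector exists for testing the rejector), volume
conduction, and the heavy-tailed amplitude statistics of real EEG.
Passing tests therefore demonstrate correctness of the pipeline's
operations and estimators under a known generative model — not that real
recordings would yield the same feature separability.

### Cohorts

`default_cohort_specs` encodes the emulated study conditions: 40 subjects
per sub-cohort; controls (C) at the branching parameter measured for the
healthy group (σ = 1.1023) and both COVID cohorts shifted down by
Δσ = 0.15; ERP amplitude scales ordered B (1.2) > A (1.0) > C (0.8) with
an 8 ms latency shift for cohort A, matching the qualitative amplitude
ordering reported on the cognitive electrodes. These effect sizes are
synthetic stand-ins — the study quantifies no effect sizes — chosen so
that one 2-minute recording yields a per-subject σ̂ standard error
(~0.05) comfortably below the injected Δσ. Per-subject seeds derive
deterministically from a master seed via named `SeedSequence` spawn keys.

## Preprocessing (`preprocess`)

Two fixed chains, both built from zero-phase (forward–backward) 4th-order
Butterworth filters so component latencies are unshifted:

* **ERP chain**: 0.1–30 Hz band-pass → optional sliding-window
  peak-to-peak artifact mask → segmentation −200..+1000 ms around onsets
  (onsets with incomplete or artifact-overlapping windows dropped) →
  baseline correction over the −200..0 ms pre-stimulus window. The
  segmentation and baseline windows follow the study's "200–1000 ms"
  segmentation and "200 ms, lasting 200 ms" baseline read as the
  pre-stimulus interval; both are configurable.
* **Classification chain**: 1 Hz high-pass → scalp-channel selection →
  45–55 Hz band-stop (line noise) → optional cleaning hook → polyphase
  downsampling to 125 Hz → common-average re-reference → 40 Hz low-pass.
  The named artifact-subspace and component-labeling algorithms of the
  original toolchain are out of scope; the cleaning hook accepts any
  Recording → Recording callable in their place.

Channel selection uses the montage's 2-D projected radius — the angle
from the vertex divided by π, so the head-circumference line sits at 0.5
(the common topographic-plot convention). On the bundled 256-channel
geodesic-net montage this retains exactly 137 channels at radius ≤ 0.5,
the count the study reports; the montage CSV carries the radius column
explicitly to avoid projection ambiguity.

The line-noise stage is contractually spectral (≥ 20 dB at 50 Hz, < 5 %
change outside the band), implemented as a band-stop rather than the
original multi-taper regression tool.

## ERP comparison (`erp_compare`)

Grand averages are computed subject-then-cohort with equal subject
weights, so subjects with more surviving trials do not dominate
(trial-weighted pooling available by flag). "Cross-correlation" is
implemented as the zero-lag Pearson correlation of two cohorts' grand
averages at one electrode — the ranking statistic behind "least
correlated electrode" reporting — with a max-|r|-over-lags variant
available as a secondary output. Correlations are always computed on
unsmoothed averages; Savitzky–Golay smoothing (local least-squares
polynomial, default window 11 samples, order 2) is reserved for plots and
reporting. Electrode ranking sorts ascending by the minimum of the three
pairwise correlations with lexicographic tie-break; peak amplitudes are
signed extrema with earlier-latency tie-break.

## Avalanche features (`avalanche`)

Detection: per-channel z-scoring over the whole cleaned recording
(population SD), events at the absolute extremum of each maximal
suprathreshold run (one event per excursion prevents duration-inflated
double counting), binning at Δt × multiplier (8 ms base — one sample at
125 Hz — multiplier 3 by default, sweep 1–10), cascade segmentation as
maximal runs of non-empty bins. Runs touching the raster edges are
censored and discarded by default.

**Size exponent.** Discrete power-law MLE: maximize
−a·Σ log s − n·log[ζ(a, x_min) − ζ(a, x_max + 1)] over a ∈ (1, 8] by
bounded scalar minimization (tolerance 1e-6); the exponent is stored with
the negative sign convention (α = −a). x_min = 1 and no x_max by
default. At least 100 sizes are required — below that the MLE variance
makes α meaningless — and all-equal sizes raise (the likelihood has no
interior maximum). The test suite checks the optimizer against an
exhaustive grid search at 1e-3 resolution on every fixture.

**Branching parameter.** σ̂ = mean over avalanches of (second-bin total /
first-bin total), with one-bin avalanches contributing 0. The zero
convention is what makes the estimator unbiased for the generator: for a
single-seed cascade the second bin is Poisson(σ), and extinction after
one bin is exactly its zero outcome, so E[σ̂] = σ for any duration cap
≥ 2.

Ambiguities resolved: the study's α/σ could be per-recording means or
pooled-avalanche fits; `compute_features` is per-recording, and
aggregation across recordings is left explicit to the caller
(`features_table` keeps one row per recording).

## Classification (`classify`)

Gaussian equal-covariance LDA, authored in-package (scikit-learn serves
only as a test oracle): class means, pooled within-class covariance with
shrinkage (1 − λ)S + λ(tr S/d)I, priors from training frequencies,
lexicographic tie-break at the decision boundary. λ defaults to 0.1
because with 2-dimensional features and small folds the pooled covariance
can be near-singular; λ = 0 is allowed and raises on singularity.

Evaluation follows the study protocol: stratified 70/30 split preserving
cohort proportions; stratified k-fold CV on the training portion — the
study's "k set to 17 %" is read as fold size ≈ 17 % of training data,
i.e. 6 folds, and `run_comparisons` clamps the fold count (with a
warning) when a training class is smaller than the fold count; the five
comparisons pool labels with the first-named side as the positive class
(A&B vs C → positives {A, B}). Metrics with zero denominators are
reported as NaN with a warning and excluded from nan-aware aggregation,
never imputed as 0 — the study's own test-set table contains a row not
jointly consistent with any single confusion matrix, which is why raw
confusion counts are always written alongside the metric tables.

## Problem sizes and seeds

Recovery experiments use 50,000 cascades (σ) and 100,000 sizes (α);
end-to-end signal recovery uses one 5-minute, 137-channel critical
recording (900 cascades); classification calibration uses 27 subjects per
cohort × 60 s (null) and 20 per cohort × 120 s (Δσ = 0.15), sizes at
which the per-subject feature SE is small relative to the injected
effect. All stochastic checks run at fixed seeds; Monte-Carlo assertions
use analytic standard errors where closed forms exist.

## Known limitations

* The branching-parameter estimate from rendered signal carries a small
  (≲ 0.03) downward bias from event collisions (two events on the same
  channel and bin merge into one excursion) and edge-censoring; the ±0.1
  end-to-end tolerance absorbs it.
* EDF files are written with a fixed epoch date (headers byte-identical
  across runs for manifest reproducibility) and 16-bit quantization; the
  round-trip error bound is one quantization step of each channel's
  physical range.
* The classification chain assumes an integer decimation factor from the
  acquisition rate to 125 Hz (true for the 250 Hz design).
* Feature separability on synthetic cohorts says nothing about effect
  sizes in real post-COVID populations; the generator's Δσ is a
  calibration device, not an empirical claim.
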