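# Methods

This note documents the models, the numerical choices, and the synthetic
data that the test suite and `scripts/acceptance.py` run on — including what
the synthetic data do and do not emulate.

## Stimulus construction

A mapping run is described by a `StimulusProtocol` (aperture diameter, bar
width, steps per sweep, step duration, sweep-direction order, blank
durations, rendering resolution) and rendered into a binary effective
stimulus: a T × H × W mask movie in visual-degree coordinates with the
checkerboard carrier deliberately omitted — only bar *position* enters the
forward model.

Conventions:

* x rightward, y upward, fixation at (0, 0).  Pixel centers sit at
  half-integer offsets so the grid is symmetric about fixation; this makes
  opposite sweep directions bit-exact frame reversals of each other, which
  the tests rely on.
* Bar centers span the aperture diameter in equal steps with the first/last
  center flush with the aperture rim (the bar is partially clipped at the
  extremes).  The flush convention is a choice — the protocol descriptions
  do not pin down whether the first position is flush or fully inside — and
  it is configurable through explicit protocol fields.
* Blank epochs are rendered as all-zero frames on the same frame raster;
  the presets use blank durations that are whole multiples of the step.
* The `fmri` preset inserts its 25 s blank after every
  horizontal/vertical (0/90/180/270°) sweep; which sweeps get blanks is
  configurable via `inter_blank_after`.

## HRF kernels

Only two timing statistics of each target kernel are known: time-to-peak
(monkey 4.2 s, human 4.8 s) and peak-to-fall (6.2 s vs 12.6 s).  The kernel
is a double gamma (positive lobe minus a delayed undershoot at 10% of peak,
undershoot scale 1.8× the positive lobe's).  Two nested 1-D root findings
pin the shape: the positive lobe's scale is solved so the *full* kernel's
derivative is zero exactly at the target peak time (the undershoot pulls
the argmax earlier, so solving the positive lobe alone is not enough), and
its shape parameter is solved so the first post-peak return of |h| to
within 5% of baseline lands at peak + peak-to-fall.  "Fall" as the
5%-of-baseline crossing is this package's operationalization (the original
statistic is not defined operationally anywhere we could follow); the
fraction is a parameter.  Kernels are unit-peak, 32 s long, and resampled
by linear interpolation.

BOLD predictions are computed at TR/2 (1.25 s for TR = 2.5 s), convolved
causally (zero-padded before run start, consistent with the pre-run blank),
truncated to the run length and decimated to the TR by averaging
consecutive sample pairs.

## Model core

The Gaussian is unit-peak, exactly as in the model definitions; the gain
absorbs all scaling.  The pixel sum Σ S·G is divided by (pixels per dva)²
so the drive approximates ∫S·G dx dy in dva² and predictions are
resolution-independent — fits must not change when the rendering resolution
changes, and a test checks 4 vs 8 px/dva agreement.  The DoG drive passes
through signed (surround suppression can push single-frame responses below
baseline); its exponent is fixed at 1, treating the static nonlinearity as
a CSS feature.  pRF size is σ/√n, the SD of the point-stimulus response
profile (verified in tests against a numerically fitted profile); DoG
center/surround sizes are σ₁ and σ₂.  The "normalized suppressive
amplitude" of a DoG fit is reported as the surround/center volume ratio
a·(σ₂/σ₁)², which makes values above 1 read as net suppression.

## Fitting

Two stages per unit and data half:

1. **Grid.** Candidate centers on a 9 × 9 lattice out to 1.5× the aperture
   radius (centers may lie outside the stimulated field), six log-spaced σ
   from 0.1 dva to the aperture diameter, exponent ∈ {0.25, 0.5, 1} for
   CSS, and two surround shapes (σ₂/σ₁ = 2, a ∈ {0.25, 0.75}) for DoG.
   The gain for each candidate is the closed-form least-squares projection
   of the prediction shape onto the data.  Candidates whose drive norm is
   below 1e−9 of the largest are discarded (their gain is numerically
   meaningless).  Top 3 candidates by training R² seed the refinement.
2. **Refinement.** `scipy.optimize.least_squares` (trust-region reflective)
   over (x₀, y₀, log σ, …, gain) with bounds |x₀|,|y₀| ≤ 1.5 × aperture
   radius, σ ∈ [0.05, 2 × aperture], n ∈ [0.05, 1.5], a ∈ [0, 3],
   σ₂/σ₁ ∈ [1.05, 20]; gain positive except U-LIN.  σ and the surround
   ratio are optimized in log space.  Tolerances 1e−10, max 200 objective
   evaluations per start.  Everything is deterministic, so refits are
   bit-reproducible.

Cross-validation splits the data into odd and even runs/repeats; each
half's fit is scored on the other half with R² = 100·(1 − SS_res/SS_tot),
SS_tot about the held-out mean (keeping the null model at 0; the
convention was left open by the source method descriptions), and the two
values are averaged.  Reported parameters come from a refit on the mean of
both halves (all the data); training R² is reported from the fold fits,
matching how inclusion thresholds are applied.  Model comparison across
units uses Kruskal–Wallis, Tukey-HSD multiple comparisons of mean rank
(Tukey's procedure applied to pooled rank-transformed R²), and pairwise
Wilcoxon signed-rank tests.

## Electrophysiology preprocessing

* **MUA envelope**: Butterworth band-pass 500–9000 Hz, full-wave
  rectification, Butterworth low-pass 200 Hz, polyphase resampling to
  1 kHz.  All filters are zero-phase forward–backward 4th-order
  Butterworth; the cutoffs are fixed by the procedure being emulated but
  the filter family/order were not specified there, so zero-phase
  Butterworth was chosen to avoid latency distortion in cRF timing.
* **LFP band power**: broadband input is low-passed at 150 Hz and
  downsampled to 500 Hz; a DPSS multitaper spectrogram (500 ms windows,
  50 ms steps, time-bandwidth NW = 5, K = 9 tapers) is averaged into five
  bands — θ 4–8, α 8–16, β 16–30, low γ 30–60, high γ 60–120 Hz — which
  partition 4–120 Hz exactly.
* **Baselining**: mean activity/power in the 1000 ms before each sweep's
  first position onset is subtracted (per-sweep, not per-run — the
  description is ambiguous; per-sweep is the default); responses are means
  over 50–500 ms after each position onset, averaged across repeats.

## Moving-bar cRF estimation

Units pass only with SNR > 3 (peak of the repeat-averaged trace minus
spontaneous mean, over the SD of spontaneous activity from inter-sweep
blanks).  Per sweep direction a Gaussian with offset is least-squares
fitted to the averaged trace; response onset/offset are the mean ∓ SD,
mapped through the bar trajectory to spatial borders.  Borders from
opposite directions are averaged, so a fixed response latency — which
shifts opposite sweeps' borders in opposite spatial directions — cancels
exactly.  Center = border midpoints; size = √(w² + h²)/2 (the SD-equivalent
radius); conventional diameter = 3.3 × size; fits with mean Gaussian R²
below 25% are rejected.

## Population statistics

* Separation index SI = center distance / (size_a + size_b); SI < 1 means
  overlap.  Sizes default to the CSS definition when taken from fit tables.
* Negative pRFs are classified by the sign of the fitted U-LIN gain.
* Eccentricity–size relations are per-unit OLS regressions (slope, 95% CI,
  p); 2-dva half-open eccentricity bins give display means ± SEM.
* Slope comparison across signal types fits `size ~ ecc × signal_type` and
  F-tests the interaction, with pairwise reference-vs-signal contrasts
  refitted per pair.  This is a fixed-effects simplification of a
  mixed-model analysis (the random-effects structure of the original was
  not recoverable); `model_backend` accepts a custom fitter, e.g. a
  mixed-effects one, as a swap-in.

## Synthetic data: what it emulates, and what it does not

Generators invert the forward models.  Populations emulate array implants
in macaque V1/V4: centers uniform over the lower-right visual quadrant
(ecc ≤ 8 dva V1, ≤ 14 dva V4), σ = intercept + slope·ecc with lognormal
jitter (defaults: intercept 0.5 dva, slope 0.1 V1 / 0.3 V4, jitter SD
0.15 in log units), CSS exponents truncated-normal around 0.35 in
(0.05, 1], gains lognormal around 1 with an optional negative fraction.
BOLD and position-response noise is additive white Gaussian; raw LFP
synthesis uses band-limited filtered-noise carriers whose amplitude is
scaled per bar position by √(1 + depth·drive); moving-bar MUA traces are
the Gaussian RF profile (broadened by the bar width) along the trajectory
plus noise.  Everything is a pure function of (parameters, seed).

Not emulated: temporally correlated (1/f) BOLD noise, neurovascular
nonlinearity, spike-count statistics, cross-electrode correlations, eye
movements, or adaptation.  Passing tests therefore demonstrate that the
estimators invert their own forward models at realistic SNR — not that
these forward models capture every property of in-vivo recordings.

## Simulation sizes and noise calibration

Recovery suites use the electrophysiology protocol rendered at 2 px/dva
(predictions are resolution-independent, so this changes runtime, not
results) with 100 units per model, 4 repeats.  Per-model noise SDs
(P-LIN/U-LIN 4.0, DoG 2.5, CSS 0.8 response units) were calibrated once so
the median training R² falls in the 60–80% band that defines the
moderate-SNR regime; recovery medians are then taken over well-fit units
(cross-validated R² > 50%, the standard electrophysiology inclusion
threshold).

## Known limitations

* Under the CSS model, σ and n trade off along a ridge for bar stimuli:
  the response bump's width constrains σ/√n tightly (the *size* is
  recovered to a few percent) while σ and n individually are much noisier.
  At moderate SNR the CSS center error also grows with pRF size; for the
  large V4-like pRFs used in the recovery suite the median center error is
  ~0.3 dva, versus well under 0.1 dva for the linear models.  Fitted
  training R² meets or exceeds that of the generating parameters on the
  same data, so this is an information limit of the stimulus design, not
  an optimizer failure.
* The DoG exponent is fixed at 1; no elliptical/oriented pRF variants.
* The slope comparison ignores hierarchical structure (units within
  arrays/animals); with strong per-array effects its F-test is
  anticonservative.
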