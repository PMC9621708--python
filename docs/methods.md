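# Methods

This note documents the models and procedures implemented in `limbspeech`,
the assumptions behind them, the choices made where the design was genuinely
open, and what the synthetic-data batteries do and do not establish.

## 1. The question and the measurement model

The hypothesis under test is mechanical: within each cycle of a biking
movement, the moment of peak limb acceleration (the *physical impulse*,
`T_accPeak`) transiently loads the respiratory system; if the impulse
exceeds some threshold, subglottal pressure — and hence speech intensity,
possibly F0 — should show a bump time-locked to the event. The analysis
therefore centres everything on acceleration-peak events and asks whether
the speech measures deviate from a straight line in the ±200 ms window
around them, and whether that deviation differs between movement conditions
(legMot, armMot) and a no-movement control (armBlock) paired with surrogate
motion.

## 2. Kinematics chain

- **Marker selection.** The pedal is found by a circularity score: the
  fraction of sagittal-plane variance explained by a least-squares (Kasa)
  circle fit, multiplied by the vertical peak-to-peak amplitude. Decoy
  markers (stationary, or drifting linearly with pedal-scale amplitude) are
  rejected by the circle-fit term.
- **Conditioning.** Linear-interpolation resampling to 100 Hz, then a
  4th-order Butterworth low-pass at 10 Hz applied forward–backward. Zero
  phase matters: every downstream quantity is an event *time*.
- **Cycle segmentation.** Position peaks with prominence ≥ 0.3 × peak-to-peak
  and separation ≥ 0.4 s; samples before the first peak are discarded
  (recordings start with a still period and run-up strokes).
- **Angle.** `asin(clip((y − midrange)/radius, ±1))` mapped to 0–180°. With
  noisy per-cycle maxima the maximum angle sits a few degrees below 180°,
  which is the expected behaviour, not an error.
- **Acceleration.** Central second differences of the filtered position at
  100 Hz, converted from cm to metres first, so magnitudes land on a m/s²
  scale (an ~8 cm crank at ~1 s cycles gives leg medians near 3.5 and arm
  medians near 2). No extra smoothing: the 10 Hz low-pass precedes
  differentiation.
- **Acceleration peaks.** Positive local maxima of the signed acceleration
  with separation ≥ 0.25 × median cycle duration, restricted to the cycled
  span. Effort modulation (two strokes per revolution) yields two such
  maxima per cycle; pure uniform rotation yields one. A `magnitude` mode
  (maxima of |a|) is available; signed maxima are the default because the
  two per-cycle effort events appear as positive maxima.

## 3. Acoustic measures

- **Amplitude envelope.** Downsample to 11,025 Hz → |analytic signal| →
  Hanning-window FIR low-pass at 5 Hz (length 2·fs/5 + 1 taps) → Gaussian
  moving average over 1,000 samples with SD = window/8 → linear resample to
  100 Hz. All stages are symmetric filters, so timing is preserved (an
  amplitude burst keeps its envelope maximum within ±20 ms). The envelope is
  z-scaled per trial before any epoching: between-trial level differences
  are dominated by mouth–microphone geometry, not speech.
- **F0.** 40 ms frames every 10 ms; normalised autocorrelation of the
  mean-removed frame; the candidate is the highest peak whose lag maps into
  the sex range (50–250 Hz male, 100–300 Hz female); voiced iff that peak
  ≥ 0.45 and frame RMS ≥ 1% of trial RMS; parabolic lag interpolation.
  Octave errors are the main residual failure mode and are what the
  per-trial asymmetric quartile filter removes (discard above Q3 + 3·IQR or
  below Q1 − 1·IQR, linear-interpolation quantiles). The filter is
  idempotent when outliers are separated from the voiced bulk; it is *not*
  idempotent in general — removing points tightens the quartiles, so a value
  just above the old cut can fall out on a second pass. Windows or epochs
  with < 50% voiced samples yield missing values.
- **Interpausal units.** Manual annotations (tab-separated intervals or a
  Praat TextGrid IntervalTier subset) or an automatic detector: envelope
  above 10% of its 95th percentile, gaps < 0.25 s bridged, intervals
  < 0.2 s dropped. Only events whose entire ±200 ms window lies inside one
  IPU are analysed; this is the strict reading of "inside speech, not in a
  pause", chosen because a partially-outside window mixes speech and
  silence samples into the epoch.

## 4. Pairing and epochs

Motion and speech streams share the trial's absolute timeline; the longer
stream is cut at the common end. Surrogate pairing for armBlock draws a
donor biking trial uniformly from the other participants' legMot/armMot
trials (equal eligibility), aligns streams at their starts, and truncates
to the shorter — under the null this preserves every marginal property of
the motion stream while destroying any speech–motion alignment. Epochs are
41 samples (−200…+200 ms at 100 Hz) centred on the grid sample nearest
`T_accPeak`; peak-window measures are means over ±25 ms (a total 50 ms
window; ±50 ms is available via a parameter). Epochs are averaged by
(participant, condition, day) before curve modelling, which tames the large
trial-to-trial variability of spontaneous speech at the cost of modelling
cell means rather than raw epochs.

## 5. Statistical models

### Peak-window mixed models

`env50 ~ accel + (1 | participant)` and
`f050 ~ accel × day × condition + (condition | participant)`, fit by REML
(statsmodels MixedLM) with normal-approximation Wald inference (peak-level
n runs into the thousands). The residual-variance-by-day correction is one
feasible-GLS pass: residual SDs per day from a first fit, responses
reweighted, refit. If the random condition-slope covariance is singular the
model falls back to a random intercept and says so. Backward selection
drops the least significant removable term by ML likelihood-ratio tests at
α = 0.05, interactions before the main effects they contain.

### Factor-smooth epoch models

Cell-mean curves are stacked and fit by penalized least squares:

- cubic B-spline bases (dimension k = 10) over the epoch window with the
  exact integrated-squared-second-derivative penalty (two-point Gauss per
  knot interval; the integrand is piecewise quadratic, so this is exact);
  the penalty null space is {constant, linear}, which is what makes
  "nonlinearity" testable;
- one centred smooth per condition (*by-condition* form) or one shared
  smooth plus per-condition deviation smooths against the armBlock
  reference (*difference* form); the envelope model carries only a global
  intercept (z-scaling removes level contrasts), the F0 model adds sex,
  day, and condition intercepts;
- random smooths per (participant, condition): B-spline deviations
  (k = 5) with penalty λ_r(S + I) sharing one λ_r, so they shrink to zero
  including their straight-line part;
- smoothing parameters by GCV (Nelder–Mead on log λ);
- residual whitening per curve. The default is a stationary AR(p) model
  (p = 6) fitted by Yule–Walker to the pooled autocovariance of residuals
  from the *unpenalized fixed* design — epoch-averaged syllabic noise is
  damped-oscillatory, which AR(1) cannot whiten, while a full empirical
  41-lag covariance is too noisy to invert at study sizes. Plain AR(1)
  (the reported ρ) and fixed-ρ modes are available.

### Hypothesis tests

The parametric tests are deliberately not read off the penalized fit.
F-ratios built from GCV-adaptive fits with edf-based degrees of freedom are
strongly anticonservative (empirical type-I error 0.13–0.19 at α = 0.05
under pure white noise in our null simulations): the smoothing parameter
chases the same noise the test then declares significant. Instead, each
test compares nested *unpenalized* regression-spline fits on the whitened
design with the random smooths excluded — classical F statistics with fixed
degrees of freedom, exact under the whitened Gaussian null:

- **Nonlinearity of a condition's curve**: that condition's spline block is
  replaced by a centred linear trend; the F numerator df is the rank
  difference (k − 2).
- **Difference from the reference**: the condition's deviation-smooth block
  is dropped. For the envelope the deviation block keeps its constant
  component (there are no condition intercepts to absorb a level shift);
  for F0 it is centred.

The penalized fit still supplies the reported edf (trace of its term-wise
influence contributions) and the fitted curves with pointwise 95% bands.
Permutation p-values (per-curve time reversal + circular shifts for
nonlinearity; condition-label swaps within participant × day for
differences) are available as a distribution-free cross-check.

This split — penalized estimation, classical testing — is the package's
resolution of a real tension: adaptive smoothing is the right estimator,
but its naive F approximation cannot hold its nominal error rate, and a
test that cannot be calibrated is not evidence. The cost is some power
against very smooth alternatives and a fixed numerator df instead of an
adaptive one.

## 6. The synthetic generator

The generator's defaults encode the study conditions the pipeline targets:

| quantity | default | basis |
| --- | --- | --- |
| roster | 22 participants (16 F), 3 conditions × 2 days | emulated study design |
| leg cycle duration | N(1.07, 0.29²) s pooled | emulated study's leg cadence |
| arm cycle duration | N(1.30, 0.37²) s pooled, ∓0.15 s by day | emulated study's arm cadence and day shift |
| variance split | within-trial SD 0.12; remainder between participants, incl. a shared-cadence component (SD 0.225) | steady per-trial cadence; drives an arm–leg cadence correlation of r² ≈ 0.3 |
| truncation | [0.4, 3.5] s | brackets the emulated study's 0.68–2.9 s range |
| crank radii | leg 8.2 cm, arm 6.9 cm | calibrated so impulse medians land at ≈3.5 / ≈2 m/s² |
| effort modulation | phase-rate modulation at 2× cycle frequency, depth 0.3 | two acceleration maxima per cycle |
| IPUs | gamma(mean 3.65 s, SD 2.28 s), +0.45 s on day 2; lognormal pauses, mean 0.6 s | emulated study's IPU statistics |
| F0 | baseline 210 F / 120 M ± 15 between participants, −4.25 Hz on day 2, −2 Hz/s declination per IPU | emulated study's day contrast; typical speaker ranges |
| syllabic modulation | raised cosine at 4 Hz ± 15%, random phase per IPU | speech amplitude envelope periodicity |
| marker noise | 0.01 cm SD | rigid-body optical tracking residual |
| coupling | gain 1 + β·Σ exp(−(t−tᵢ)²/2w²) at peaks with magnitude ≥ threshold; defaults β = 0.3, w = 40 ms, threshold 3.4 m/s² | the threshold hypothesis made concrete; 3.4 sits just below the leg median because the hypothesised threshold exceeds typical arm impulses |

Kinematics are generated from a continuous phase law: the instantaneous
period interpolates the drawn per-cycle durations at cycle midpoints (so
pedal velocity is continuous across cycles), and ground-truth cycle and
acceleration-peak events come from the same analytic phase on a 1 kHz grid
— the generated events are local maxima of the sampled analytic
acceleration to within one 200 Hz sample.

Two output modes:

- **audio**: harmonic source (8 harmonics, 1/k rolloff) with the F0
  contour, syllabic × coupling amplitude modulation, −50 dB noise floor,
  PCM16 WAV at 44.1 kHz — exercised end-to-end by the extraction chain;
- **tracks**: the 100 Hz envelope (syllabic × gain + AR(1) measurement
  noise, ρ = 0.6, SD 0.12, plus a per-trial lognormal microphone gain that
  z-scaling must remove) and F0 (truth + 1.5 Hz tracking error + 10%
  unvoiced dropouts) emitted directly. Simulation batteries run in track
  mode; synthesising hundreds of full audio studies is not informative for
  the statistics being calibrated and would dominate the runtime.

What track mode does **not** emulate: real spectral tilt and formants,
coarticulation, pause-internal breath noise, annotator disagreement about
IPU boundaries, marker occlusions. Passing batteries therefore validate
the event logic and the statistics, not robustness to those artifacts.

## 7. Simulation batteries and what they show

- **Null calibration** (400 zero-coupling studies, 6 participants, 60 s
  trials, 2 days): empirical rejection of every smooth test at α = 0.05
  falls in [0.02, 0.09], and the envelope LMM's 95% CI covers the true
  (zero) acceleration coefficient at ≈95%.
- **Effect recovery** (100 coupled studies, 22 participants): the injected
  β = 0.3 is recovered from grand-average raw-envelope epochs to within a
  few percent (estimator: fit grand(t) = B(1 + β·s̄(t)), where s̄ includes
  the kernels of neighbouring coupled peaks — at fast cadences the second
  effort peak sits only ~0.2 s away, so no flat off-peak baseline exists —
  conditioning on events that clear the threshold by a 0.4 m/s² margin,
  since near-threshold events are ambiguous under measurement noise). The
  legMot–armBlock difference smooth is significant in ≥ 95% of replicates.
- **A documented limitation**: the armMot–armBlock contrast is *not*
  reliably null. With the cycle-duration spreads above, impulse magnitude
  scales as R/T², so ~20–27% of arm impulses exceed any threshold placed
  between the arm and leg medians; armMot genuinely couples at ~40% of the
  leg rate, and the difference test (correctly) detects that in ~30% of
  replicates. No study size separates the two conditions cleanly — the
  noncentrality ratio is ~4 where ≥6 would be needed. A hard per-event
  magnitude threshold between the medians is therefore *incompatible* with
  a cleanly leg-only effect under these cadence distributions; a clean
  dissociation requires either a higher threshold, participant-level
  gating, or narrower impulse distributions. The package reports this
  honestly rather than engineering the generator around it.

## 8. Numerical details and degenerate inputs

- Quantiles: linear interpolation between order statistics, recorded in
  track metadata.
- Spline fits add a 1e-10 ridge before Cholesky; singular random-effect
  covariances trigger a documented fallback, not a crash.
- Degenerate inputs raise early with specific messages: trials shorter than
  one cycle, no circular marker above 1 cm amplitude, > 0.5 s marker
  dropout, rotation radius < 0.5 cm, zero-variance envelopes, F0 baselines
  outside (50, 400) Hz, surrogate pools containing only the speaker's own
  trials, < 5 s of speech–motion overlap.
- All randomness flows from explicit seeds; per-trial streams derive from
  (study seed, participant, day, condition), so any single trial is
  reproducible in isolation and study outputs are byte-identical across
  runs.
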