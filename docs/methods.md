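# Methods

This note documents the generative model, the analysis conventions, the
numerical choices, and the known limits of what the simulation-based
tests demonstrate.

## Task geometry and units

Two orientation stimuli are encoded left and right of fixation at ±8°
horizontal eccentricity. All gaze positions are expressed in *normalized
units*: fixation = 0 and the stimulus centres map to ±100, so 12.5 units
≈ 1°. Times are integer milliseconds on a 1000 Hz grid; epoch time 0 is
retro-cue onset; all windows are half-open `[start, end)`. Rightward and
upward are positive.

Trial structure (Experiment 1): variable 500–800 ms intertrial interval,
two 250 ms encoding displays separated by 750 ms, a 1250 ms delay, a
250 ms colour retro-cue, and a second 1250 ms delay ending in the go
signal. Five presentation subtypes (three simultaneous, two sequential)
occur equally often — 100 trials each in 10 blocks of 50 by default.
Experiment 2 always presents items sequentially and cues them by colour
or by temporal order; 480 trials over 5 + 5 blocks.

## Generative model

The simulator synthesizes gaze in normalized units as a sum of
components, then maps to tracker units through a per-axis affine
(`normalized = gain·(raw − offset)`) so the calibration stage has
something real to recover.

**Drift and noise.** Slow drift is an Ornstein–Uhlenbeck process with
stationary SD 2 units and mean-reversion θ = 2·10⁻⁴ per ms (correlation
time ≈ 5 s), giving drift velocities of roughly 1–2°/s through the
velocity filter. Measurement noise is white, 0.2 units RMS (~0.016°) per
eye and independent between eyes, in the range of a well-calibrated
video eye tracker. Per-trial baseline correction removes accumulated
drift offsets.

**Microsaccades.** Candidate events arrive as a Poisson process at
1.5 Hz with log-normal amplitudes (median 5 units, σ_log 0.6 — ~92% of
amplitudes below 12.5 units, i.e. below 1°). The displacement waveform
is a C¹ smoothstep over 20 ms (velocity peak mid-flight); any smooth
unimodal profile would serve the threshold detector equally. A 50 ms
refractory interval thins candidates that would start too soon after the
previous saccade's offset — real intersaccadic intervals almost never
undercut this — which also keeps detection unambiguous. These oculomotor
constants are free parameters of the generator (no numeric values are
available to pin them); they are chosen once for plausibility and all
recovery tests are run under them.

**Direction bias.** Outside the post-cue window saccade direction is a
fair coin. Within 1500 ms after the cue, the probability that a saccade
heads toward the cued item's encoded side is
`p(t) = 0.5 + (p_peak − 0.5)·b(t)` with `b` a gamma-shaped bump
(`b = u² e^{2(1−u)}`) that is zero before `bias_latency_ms` (default
300 ms) and rises to 1 at an internally derived time. Each biased-window
saccade spawns, with probability 0.9, a return saccade of equal and
opposite displacement after an exponential delay (mean 300 ms) from its
offset. Returns head back to centre, i.e. *away* from the cued side, and
produce the late negative lobe of the toward-minus-away rate.

`bias_peak_ms` (default 600 ms) parameterizes the peak time of the
*expected position bias* — the quantity towardness measures. Because
returns progressively cancel earlier displacements, the position bias
peaks later than the direction-probability bump. The generator therefore
derives the bump's peak by bisection against the convolution of `b` with
the return-survival kernel
`S(s) = (1 − q_eff) + q_eff·e^{−(s−d)/τ}` (d = saccade duration, τ =
return delay mean, q_eff = return probability discounted by the
first-order chance a return is thinned by the refractory rule). Group
recovery runs at default parameters place the measured towardness peak
within ±100 ms of the configured 600 ms.

**Mirror construction.** `simulate_session(..., mirror=True)` flips every
cued side while consuming identical random draws, so each biased
displacement reverses sign exactly; expected towardness negates. The
analysis-side counterpart, `metrics.mirror_epochs`, swaps the cue labels
only — relabelling the cue negates towardness identically, whereas
mirroring labels *and* geometry would leave it invariant.

**Blinks and calibration.** Blinks are Poisson (0.04 Hz, 100 ms), set all
channels missing, corrupt 50 ms of samples on each side (a half-cosine
artifact mimicking partial pupil occlusion), and emit BLINK markers. Each
session begins with a 7-point calibration sweep (centre, ±100 horizontal,
±60 vertical, two diagonals) visited in random order for 1.2 s each.

## Preprocessing conventions

* **Blink interpolation** widens each blink by 50 ms per side and fills
  the gap with a cubic spline anchored on 100 ms of flanking clean data.
  Gaps over 500 ms are nearest-filled and flagged; trials overlapping
  them are excluded as gaze artifacts (long gaps are unrecoverable).
  Blinks abutting a recording edge fall back to nearest-value fill.
* **Calibration** regresses the per-point median gaze over 400–1000 ms
  after each calibration-point onset, per axis, onto the nominal target
  coordinates; fixation maps to 0 and the stimulus-centre targets to
  ±100. Noise-free input recovers a known affine to ≤10⁻⁶.
* **Binocular combination**: the two eyes are averaged per axis after
  interpolation; if one eye is missing the other is used. (The recording
  is binocular but no combination rule is dictated by the data; averaging
  is the variance-optimal default.)
* **Epochs** span −500…1499 ms around the cue; each channel's per-trial
  mean over [−500, 0) is subtracted.
* **Exclusions**: (a) trials in which |horizontal gaze| exceeds 50 units
  at any sample in [0, 1500) — the post-cue analysis window; baseline
  noise should not void a trial — and (b) trials with response onset
  above mean + 4 SD of the remaining trials, reapplied until stable.
  Note the 4 SD rule cannot flag anything below n ≈ 18 (the maximum
  achievable z in a sample of n is (n−1)/√n). Both the axis choice and
  the window of rule (a) are configurable. The rules are idempotent.
  The time × magnitude analysis runs on trials filtered by rule (b)
  only, so that large return-to-location shifts would remain visible.

## Saccade detection

Velocity is estimated with the 5-sample symmetric difference filter
`v_t = (x_{t+2} + x_{t+1} − x_{t−1} − x_{t−2}) / 6Δt`. A per-trial,
per-axis threshold is λ = 5 median-based SDs
(`sqrt(median(v²) − median(v)²)` ≈ 0.674σ for Gaussian noise, making the
effective threshold ≈ 3.4σ), combined across axes by the elliptic
criterion `(v_x/η_x)² + (v_y/η_y)² > 1`. Supra-threshold runs shorter
than 6 ms are discarded *before* nearby runs (≤ 20 ms apart) are merged
— the ordering matters: single-sample noise exceedances at a 3.4σ
threshold are common enough to corrupt onsets if merged first. Event
displacement is horizontal only (`dx = x_offset − x_onset`; the stimuli
are separated horizontally), and events with |dx| ≤ 1 unit are dropped.
Events touching the epoch edges are discarded (displacement undefined).
On low-noise simulated sessions the detector recovers ≥95% of injected
saccades of amplitude ≥3 units with ~1 ms mean onset error; at default
noise, small-amplitude events below the adaptive threshold are missed,
as with any velocity criterion on real data.

**Rates.** Onset counts per 1 ms bin are divided by trial count and
scaled to Hz, then smoothed with a centred 100 ms moving average whose
window shrinks at the epoch edges. Unsmoothed rates integrate exactly to
events per trial; smoothing preserves this away from the edges.

## Statistics

* **Paired/one-sample t** on condition differences; Cohen's
  *d* = |t|/√n; 95% CI from the t quantile.
* **Cluster permutation**: sample-level paired t values beyond the
  two-sided p < 0.05 threshold (|t| > t₀.₉₇₅,df — the conventional
  default; configurable) form contiguous same-sign clusters scored by
  summed t. The null is the per-permutation maximum cluster mass under
  random sign flips of whole participant difference curves, kept
  separately per sign and tested at α = 0.025 per side. Monte-Carlo
  p-values use the (b+1)/(m+1) convention; an exact mode enumerates all
  2ⁿ sign patterns for n ≤ 20. Familywise error calibrates to 0.05 on
  null simulations, and boundaries/masses agree with an independent
  implementation (MNE) exactly.
* **JZS Bayes factors**: bf01 = central-t density over the marginal of
  the noncentral-t density under a Cauchy(0, r) prior on the
  standardized effect, integrated by adaptive quadrature (relative
  tolerance 10⁻¹⁰, so 2-decimal outputs are stable; agreement with
  pingouin's closed-form route is ≤10⁻⁶ relative). bf01 > 1 favours the
  null; bf10 = 1/bf01. Default scale r = 0.707 with a
  {0.5, 1, 2} sensitivity sweep.
* **Power sensitivity**: smallest d with two-sided one-sample power ≥
  the target at given n, solved by bisection on the noncentral-t
  distribution (the opposite-tail term is nan-guarded where scipy
  underflows at large noncentrality).

The delay-period scalar for each participant and condition is the mean
of the time course over [0, 1500) ms — cue onset to epoch end, the only
self-consistent reading of "the entire delay period".

## Problem sizes in tests

The test suite runs everything on simulated data sized to what each
property needs: detector scoring uses one 80-trial low-noise session;
towardness latency/peak recovery uses 8 participants × 500-trial
sessions; familywise-error calibration uses 200 null groups of 20
participants × 100 time points at 1000 sign flips; exact-vs-Monte-Carlo
cluster agreement uses n = 5 (32 enumerable sign patterns). These sizes
were chosen so each check is decisively powered for its tolerance.

## What the simulations do and do not show

The generator reproduces the statistical structure the analysis assumes:
drift + noise + threshold-detectable microsaccades, a latency-then-peak
direction bias, return saccades, blinks, and affine raw units. It does
not model oculomotor physiology (main-sequence amplitude–velocity
scaling, binocular conjugacy, saccadic suppression), vertical direction
biases, pupil dynamics, or participant heterogeneity beyond independent
random streams. Passing recovery tests therefore validates the
*pipeline* — detection, normalization, metrics and inference — under
known ground truth; it does not certify detector performance on any
particular human dataset, where noise spectra and saccade kinematics
differ. Likewise the familywise-error calibration shows the permutation
machinery is correct under exchangeability, not that real condition
time courses satisfy its assumptions.
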