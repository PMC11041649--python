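# gazecraft

Simulation and analysis of fixational gaze biases during attentional
selection from visual working memory.

When people hold two objects in working memory — one encoded left, one
encoded right of fixation — and a non-spatial retro-cue later tells them
which object will be probed, their gaze becomes subtly biased toward the
cued object's *encoded* location, even though nothing is ever shown there
again. The bias is carried by microsaccades (gaze shifts well below 1°)
and is a behavioural index of space-based attentional selection within
memory. `gazecraft` implements the complete analysis chain for this kind
of experiment, together with a generative simulator of fixational eye
movements that makes every stage testable against known ground truth —
useful for method development, power exploration, and teaching, without
access to human recordings.

## What it computes

Gaze is normalized so that fixation is 0 and the stimulus centres at ±8°
map to ±100 units, using a per-axis affine fit to 7-point calibration
sweeps. After blink interpolation, epoching (−500…1499 ms around the cue),
baseline correction and trial exclusion, the pipeline derives:

* **Towardness** — the signed gaze-position bias,
  `T(t) = (mean x, right-cued − mean x, left-cued) / 2`,
  positive when gaze leans toward the cued item's encoded side.
* **Saccade-rate effect** — microsaccades are detected by adaptive
  velocity thresholding (5-sample velocity filter, threshold λ = 5
  median-based SDs, elliptic 2-D criterion), classified toward/away from
  the cued side, and summarized as smoothed onset-rate time courses (Hz)
  and their contrast, plus a time × magnitude bias map (bins of 4 units
  from 2 to 110).
* **Group inference** — cluster-based sign-flip permutation tests on the
  time courses (max cluster-mass null, α = 0.025 per side), paired
  t-tests with Cohen's *d* = |t|/√n on delay-period averages, and JZS
  Bayes factors (Cauchy prior on the standardized effect, scale
  r ∈ {0.5, 0.707, 1, 2}) quantifying evidence for the null, with the
  noncentral-t power solver used for design sensitivity analyses.

The simulator generates raw binocular recordings (drift + measurement
noise + log-normal-amplitude microsaccades + blinks + calibration sweeps)
in which post-cue microsaccade direction follows a gamma-shaped
probability bump rising ~300 ms after the cue, with return-to-centre
saccades producing the characteristic late negative rate lobe. Ground
truth for every injected event is returned alongside.

## Worked example

```
$ cat cfg.yaml
experiment: 1
seed: 1
n_participants: 8
sim:
  n_trials_per_subtype: 60
n_permutations: 2000

$ gazecraft run-all --config cfg.yaml --out out/
report written to out/
$ gazecraft report --out out/
experiment 1, n=8
  saccade_effect:sequential-simultaneous: t(7) = -1.55, p = 0.166, d = 0.55
  towardness:sequential-simultaneous: t(7) = 0.45, p = 0.667, d = 0.16
  BF01[towardness:sequential-simultaneous, r=0.5] = 2.17
  BF01[towardness:sequential-simultaneous, r=0.707] = 2.73
  BF01[towardness:sequential-simultaneous, r=1.0] = 3.56
  BF01[towardness:sequential-simultaneous, r=2.0] = 6.56
  BF01[saccade_effect:sequential-simultaneous, r=0.5] = 1.10
  BF01[saccade_effect:sequential-simultaneous, r=0.707] = 1.24
  BF01[saccade_effect:sequential-simultaneous, r=1.0] = 1.48
  BF01[saccade_effect:sequential-simultaneous, r=2.0] = 2.41
```

Eight simulated participants completed 300-trial sessions in which both
conditions share the same gaze-bias profile. The within-condition cluster
tests (in `out/summary.json`) find the injected bias — e.g. a positive
towardness cluster from 518–1297 ms (p = 0.004) in the simultaneous
condition — while the condition contrasts are null: small t values and
Bayes factors above 1 that favour "no difference", growing with the prior
scale, exactly the pattern such a generator should produce. `out/` also
contains tidy CSVs of all time courses, delay-period averages, behaviour
summaries, exclusion tallies and the full Bayes-factor table.

The CLI stages (`simulate`, `preprocess`, `analyze`, `run-all`, `report`)
are thin wrappers; everything is importable from
`gazecraft.{simulate,preprocess,saccades,metrics,stats,pipeline}`.

## Layout

```
src/gazecraft/
  gaze_io.py      plain-text recording dialect, trial tables, reports
  simulate.py     generative model + ground truth
  preprocess.py   blinks, calibration, normalization, epochs, exclusions
  saccades.py     detection, direction, rate and magnitude time courses
  metrics.py      towardness, reproduction error, behaviour summaries
  stats.py        paired t / Cohen's d, cluster permutation, JZS BF, power
  pipeline.py     orchestration; cli.py: command-line entry points
docs/methods.md   model and analysis documentation
tests/            pytest suite (unit, property and acceptance tests)
```
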