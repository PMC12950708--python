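# gazereach

Simulation and analysis of **anticipatory gaze in reach-to-grasp tracking
under a directional movement bias**.

## The scientific problem

When people grasp a moving target whose direction is uncertain, the
visuomotor system can exploit the target's *movement history*: if the target
moved rightward on 75% of recent trials, gaze drifts toward the anticipated
leading edge before the target even starts to move. This package implements
the full analysis pipeline for that paradigm — for researchers studying
statistical learning in oculomotor and reach control who want a tested,
reusable implementation that runs end-to-end on synthetic data with known
ground truth.

The task: a 7.00 × 3.50 cm target (8.02° × 4.01° at 50 cm) appears at
screen centre, stays put for 2.5 s, then translates horizontally at 15 cm/s
(17.19°/s). A go tone at 3.0 s cues a reach-to-grasp; the target stops when
the index finger comes within 0.5 cm of the screen. A session is a no-bias
block (12 left / 12 right experimental trials + 8 timing distractors)
followed by two 75/25 biased blocks (18/6 + 6/2), pseudorandomized under
adjacency constraints.

## What the package computes

- **design** — constraint-satisfying block/trial sequences (rejection
  sampling; composition and adjacency guaranteed).
- **simulate** — per-trial gaze (250 Hz), hand (100 Hz) and target time
  series with injected ground-truth events; cohort-level random effects.
- **geometry** — small-angle conversions, stream fusion (linear
  interpolation onto the gaze grid), moving-average + central-difference
  differentiation.
- **events** — saccades by velocity (> 35°/s) + acceleration (> 1000°/s²)
  thresholds; fixations by the I-DT dispersion algorithm (≥ 100 ms, ≤ 1 cm);
  reach onset at the sustained 5 cm/s wrist-speed crossing; screen contact;
  calibration-check errors.
- **metrics** — the per-trial dependent variables with the signed-ahead
  convention: anticipatory gaze deviation

  `dev = mean over t ∈ [0, 2.5 s) of (gaze_x − target_x) · sign(direction)`,

  catch-up saccade amplitude/duration, post-catch-up and reach-onset
  fixation deviations, peak reach velocity, reach duration and latency;
  exclusion rules (premature reach, missed grasp, target escape).
- **stats** — split-plot mixed ANOVA with partial η², Greenhouse–Geisser ε
  and Mauchly's test; paired/independent comparisons with a Shapiro–Wilk
  selected Wilcoxon fallback; random-intercept linear mixed models

  `y_ij = β₀ + β₁·gaze_ij + β₂·block_ij + β₃·bias_i + b_i + ε_ij,  b_i ~ N(0, σ_b²)`

  estimated by profiled REML, with a robust variant (iteratively reweighted
  REML, Huber ψ, c = 1.345) whose significance is judged by 95% CI exclusion
  of zero.

## Worked example

```python
from gazereach import CohortParams, analyze_cohort, calibration_table, stats_report
from gazereach.metrics import summarize

params = CohortParams()                      # 50 participants, 25 per bias group
trials = analyze_cohort(params, design_seed=1)   # simulate + detect + measure (~30 s)
summaries = summarize(trials)

rep = stats_report(trials, calibration_table(params, 1))
a = rep.anovas["anticipatory_deviation"].effects["within"]
print(f"F({a.df1:.0f}, {a.df2:.0f}) = {a.F:.2f}, p = {a.p:.4g}")
print(rep.mixed_models["catchup_amplitude"].summary())
```

Output (design_seed = 1):

```
          anticipatory_deviation  catchup_duration_ms  peak_reach_velocity
biased_1                   -0.04                30.17                83.89
biased_2                   -0.45                28.39                80.98

Trial Block effect on anticipatory deviation: F(1, 48) = 10.27, p = 0.002408
Excluded: 6.31% of experimental trials

Robust linear mixed model (2242 obs, 50 participants)
Random intercept SD = 0.841, residual SD = 0.970
Fixed effect            Estimate  Std. error  Lower 95% CI  Higher 95% CI
intercept                   7.40        0.18          7.05           7.76 *
anticipatory_gaze          -0.94        0.03         -1.00          -0.89 *
biased_block                0.40        0.04          0.31           0.48 *
directionality_bias        -2.63        0.25         -3.13          -2.14 *
```

Reading this: the pipeline-measured anticipatory deviations recover the
generator's block structure (early biased block near zero, late block
drifting to −0.45 cm, i.e. the gaze strategy change across blocks), the
trial-block ANOVA detects that change at the cohort size the design calls
for, the exclusion machinery recovers the injected 6.1% bad-trial rate, and
the robust mixed model flags anticipatory gaze as a significant negative
predictor of catch-up saccade amplitude — more anticipation, smaller
corrective saccade. A `*` marks predictors whose 95% CI excludes zero.

There is also a CLI:

```bash
gazereach run-all --n-participants 10 --seed 1 --out results/
gazereach design --seed 2 --out designs/     # just the trial sequences
```

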