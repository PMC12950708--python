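# Methods

This note documents the generative model, the detection conventions, the
statistical estimators, and the design decisions behind them — in enough
detail that a user can judge what a passing test suite does and does not
establish about real eye-tracking data.

## Task model and coordinate conventions

All positions live in a screen-centered frame: x positive rightward, y
positive upward, units cm; hand channels add z, the distance from the
screen plane. Angular quantities use the small-angle convention
`deg = (cm / d)·180/π` at viewing distance d = 50 cm. This is the
convention under which the task's printed geometry is self-consistent
(7.00 cm ↔ 8.02°, 15 cm/s ↔ 17.19°/s); the full-tangent formula
`2·atan(s/2d)` gives 8.01° and would make the detection thresholds
inconsistent with that arithmetic. Detection operates in cm; conversion to
degrees happens only where a threshold is stated in degrees.

Every gaze deviation is signed: positive means ahead of the target's
horizontal midline *in the direction of the eventual target movement*.

## Session design

A session is three 32-trial blocks: no-bias (24 experimental, 12/12 by
direction; 8 timing distractors, 4/4), then two blocks biased 75/25 toward
the participant's group direction (18/6 experimental, 6/2 distractors).
Timing distractors play the go tone at motion onset (2.5 s) instead of
3.0 s and are never analysed. Ordering is pseudorandomized by rejection
sampling — shuffle uniformly, reject orders violating the constraints, with
a 10,000-attempt bound that is never approached in practice (acceptance
rates are roughly 5–15%). Constraints: no more than two consecutive
same-direction trials in the no-bias block; no two consecutive
opposite-to-bias trials in biased blocks. Both are enforced over the full
32-trial stream (experimental and distractor trials jointly), since the
participant experiences them as one sequence; whether distractors counted
toward the rule is not specified by the task description, and the joint
reading is the stricter one.

## The synthetic cohort

The simulator's defaults *are* the study conditions: every block-level
parameter is set to the corresponding observed block summary, so that the
pipeline's job — recovering those numbers from raw time series — is well
posed.

| quantity | no-bias | biased 1 | biased 2 | source of default |
|---|---|---|---|---|
| anticipatory deviation mean (cm) | 0.06 | 0.12 | −0.44 | block summaries |
| anticipatory between-SD (cm) | 0.20 | 0.67 | 0.70 | back-solved, see below |
| catch-up duration mean (ms) | 30.11 | 30.11 | 28.20 | block summaries |
| peak reach velocity (cm/s) | 86.54 | 86.54 | 83.31 | block summaries |
| reach duration (s) | 0.54 | 0.54 | 0.54 | block summaries |
| reach latency (s) | 0.97 | 0.97 | 0.96 | block summaries |
| post-catch-up fixation offset (cm) | −1.0 | R +0.18 / L −2.41 | R +0.53 / L −1.74 | group × block summaries |
| reach-onset fixation offset (cm) | −1.4 | R −1.60 / L −1.17 | R −1.35 / L −0.92 | fitted-model coefficients |
| trial-failure rate | 0.061 | 0.061 | 0.061 | reported exclusion rate |

Only participant-level *summary* SDs are observable, so each dispersed
quantity is split once into a between-participant SD and a within-trial SD
such that the SD of participant block means (between² + within²/n_trials)
reproduces the printed summary SD — e.g. anticipatory within-SD 0.6 cm with
per-block between-SDs 0.20/0.67/0.70 cm reproduces block-mean SDs
0.24/0.68/0.71 cm. Gaze sample jitter defaults to 0.03 cm RMS,
inside the tracker's stated < 0.05° spatial resolution. Calibration-check
errors are participant offset (mean −0.03 cm, between-SD 0.16 cm) plus
per-check noise (SD 0.30 cm), chosen once to approximate the reported
displacement and absolute-error summaries; no decomposition of those is
published.

Two defaults are deliberate departures from the physical rig, both forced
by internal arithmetic of the task description itself:

- **Screen half-width 36 cm.** A 24-inch 16:9 monitor is ~53 cm wide, but
  at the mean timing parameters (tone 3.0 s + latency 0.97 s + duration
  0.54 s) the target centre is ~30 cm from screen centre at contact — off a
  physical monitor. The simulated screen is widened so that trials
  generated at the default parameters are not spuriously excluded as
  "target escaped"; the escape rule itself is exercised with narrower
  screens in tests.
- **Saccade latency 0.25–0.35 s after motion onset** (mean 0.30 s, not a
  published quantity). This value makes the fixation-offset summaries and
  the centimetre scale of catch-up amplitudes mutually consistent, and
  guarantees the catch-up saccade clears the 100 ms detection window.

### Trial rendering

*Gaze.* An anticipatory fixation at the signed offset until motion onset +
saccade latency; then a catch-up saccade to the first tracking plateau;
then **step-and-hold tracking**: 0.28 s fixation plateaus separated by
small transition saccades, until contact, after which gaze rests. Each
plateau's position is the target midline at the plateau's midpoint time
plus the signed offset, so the injected offset is exactly what the metrics
layer measures at that fixation. Step-and-hold is an idealisation: real
pursuit at 15 cm/s would never satisfy a 1 cm / 100 ms dispersion
criterion, so continuously pursuing synthetic data would contain *no*
I-DT fixations at all — the paradigm's reactive fixation measures only
exist for step-like tracking.

Saccades are rendered as grid-aligned position ramps whose first and last
steps are 1.2 cm (outside the 1 cm I-DT capture radius) with uniform
middle steps. Sharp edges make the detector's boundary placement exactly
predictable (see below) and keep fixation windows from swallowing saccade
tails. A per-saccade amplitude floor (2.4 cm + 0.15 cm per middle sample)
guarantees detectability; when a drawn fixation offset would imply a
smaller saccade the landing is pushed out to the floor, which compresses
extreme trailing offsets by ~0.1–0.2 cm in the leftward group — visible in
recovery tests as a small conservative bias of the group asymmetry, and
accepted as the price of sample-exact event recovery.

*Hand.* A minimum-jerk reach along a straight 3-D path. The path length is
set by the drawn peak velocity (`peak = 1.875·D/T`), and the movement's
start time and total duration are solved (fixed point) so that the wrist
speed crosses 5 cm/s exactly at tone + latency and the index marker crosses
the 0.5 cm contact plane exactly at onset + duration. Ground truth
therefore stores the *detectable* onset — the 5 cm/s crossing — matching
the task's operational definition of movement onset.

*Failures.* With probability 6.1% a trial is rendered incorrectly: half
premature reaches (onset 0.25 s before the tone), half missed grasps
(contact 4.6 cm beside the target centre). The exclusion rules must
recover both the rate and the reason.

## Detection conventions

- **Differentiation**: 5-sample (20 ms at 250 Hz) centered moving average,
  then a two-point central difference; endpoints one-sided; acceleration is
  the same operator applied to speed. The window is a parameter (3 and 7
  are the sensitivity settings); no filtering scheme is prescribed by the
  task description, and 5 samples is the smallest window that keeps a
  ~28 ms saccade resolvable while suppressing jitter-driven acceleration
  noise (at 0.03 cm jitter the acceleration noise SD is ≈ 300°/s², safely
  under the 1000°/s² threshold).
- **Saccades**: cores where angular speed > 35°/s, extended over adjacent
  samples with |acceleration| > 1000°/s², runs merged when separated by
  fewer than 2 samples. The moving-average + central-difference cascade
  spreads a motion edge over `window//2 + 1` samples per side, so reported
  boundaries are corrected inward by that operator half-width: a sharp
  movement spanning K sample intervals is reported with duration exactly
  K/rate, which is what makes the injected duration distribution
  recoverable without bias despite 4 ms quantisation. A 0.5 cm minimum
  amplitude discards jitter blips.
- **Fixations**: classical I-DT — grow a 100 ms window, qualify when the
  dispersion (sum of x and y ranges, the Salvucci–Goldberg metric; max
  pairwise distance available as an option) is ≤ 1 cm, extend maximally,
  emit, restart after the window. Verified boundary-exact against a
  brute-force oracle.
- **Reach onset**: first upward 5 cm/s wrist-speed crossing sustained for
  ≥ 50 ms (debounce, a parameter). The search spans the whole trial so
  premature reaches surface. **Contact**: first sample with the index
  marker within 0.5 cm of the screen, evaluated after fusing the hand
  stream onto the gaze grid.
- Masked (NaN) samples split every detector's input; nothing is
  interpolated across gaps.

## Metrics and exclusions

Anticipatory deviation averages *all* valid gaze samples in [0, 2.5 s)
(saccadic samples included; a fixations-only variant exists). Reactive
deviations are measured against the target's position at the event's
reference time — the fixation midpoint for the post-catch-up fixation, the
reach-onset time for the reach-onset fixation — because the target moves
during reactive events. Participant × block summaries average included
experimental trials; by default both movement directions contribute under
the eventual-direction sign convention, with a bias-direction-only mode as
the documented alternative. Exclusions, in order: premature reach (onset
before tone), missed grasp (contact outside the 7 cm target extent),
target escape (centre beyond the screen edge before contact); trials whose
events cannot be measured at all are classed as equipment failures.

## Statistics

- **Split-plot mixed ANOVA** (one between-subjects factor, one repeated
  factor) from explicit cell-mean sums of squares; between effects tested
  against subjects-within-groups, within/interaction against the
  block × subject error; partial η² = SS_effect/(SS_effect + SS_error).
  Greenhouse–Geisser ε comes from the pooled within-group covariance of
  the repeated measures; with 3+ levels the correction multiplies both df
  when Mauchly's test rejects at α = 0.05 (an always-correct mode exists).
  Verified against pingouin and against hand-computed decompositions; SS
  conservation holds to 10⁻¹⁰ relative.
- **Paired comparisons** select the paired t or the Wilcoxon signed-rank by
  a Shapiro–Wilk test on the differences at α = 0.05 (the selection rule is
  a formalisation; "when necessary" is the stated policy). The Wilcoxon
  drops zero differences, uses the exact distribution up to n = 25 and the
  continuity-corrected normal approximation (reporting z) above. Group
  comparisons use the pooled-variance t with df = n₁ + n₂ − 2.
- **Random-intercept mixed models** are REML-estimated by profiling the
  variance ratio λ = σ_b²/σ²: for fixed λ the GLS solution is closed-form
  via the compound-symmetry block inverse, so the 1-D profile likelihood is
  optimised directly. Verified against statsmodels MixedLM to ~10⁻⁵
  relative on coefficients. The robust variant iterates reweighted REML
  with Huber ψ (c = 1.345) on scaled residuals *and* scaled random
  effects, with Huber Proposal-2-style scale updates and a variance
  inflation κ/E[ψ′]² on the Wald covariance. This is a design-weight
  approximation to fully robust estimators (the DAStau estimator is not
  re-derived); it is validated by recovery and contamination-robustness
  simulations, not by coefficient matching. Significance of a predictor is
  CI-based: 0 outside the Wald 95% interval. Models run at trial level
  (block-aggregated responses would leave the random intercept
  near-degenerate); reference levels are the first biased block and the
  rightward group.

## Problem sizes in the test suite

The suite validates at the scales the analyses are designed for: the
parameter-recovery study runs one full 50-participant cohort (4,800
simulated and detected trials) plus 200 generator-level replications for
ANOVA power; the I-DT oracle comparison uses 1,000 random traces; duration
recovery uses 1,000 saccades; CI coverage uses 300 model fits. The whole
suite completes in well under a minute on one core because detection is
O(n) per trial and the profiled REML is closed-form per candidate λ.

## What passing tests do and do not show

The simulator reproduces the *statistical structure* the analysis assumes:
block-level means/SDs, event geometry, exclusion rates. It does not model
main-sequence saccade dynamics, smooth pursuit proper, blink artifacts
(beyond an optional gap injector), grip aperture, head movement, or
calibration drift within a session. Event-recovery results therefore
certify the detectors' implementation — thresholds, window logic, boundary
conventions — not their field performance on noisy human data, where
filtering choices and the unmodelled behaviours above dominate. Likewise,
the robust-model validation certifies estimator behaviour under the
contamination model used (gross one-sided errors), not equivalence with any
particular published estimator.

Mixed-model coefficients from synthetic cohorts are *not* expected to match
the fitted values that motivated the offset defaults: synthetic catch-up
amplitudes are anchored to fixation-midpoint geometry and are systematically
larger than their empirical counterparts. The recovery targets are the
quantities the generator actually injects.
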