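"""End-to-end orchestration: simulate → detect → metrics → stats.

The cohort runs as a stream — each trial is rendered, analysed and reduced
to one metrics row before the next is touched — so memory stays flat at any
cohort size.  ``stats_report`` assembles the full inferential battery on the
resulting tables: calibration-accuracy ANOVAs, baseline group comparisons in
the no-bias block, 2 × 2 mixed ANOVAs across the biased blocks, paired block
comparisons of the reach kinematics, and the four robust random-intercept
models predicting reactive behavior from anticipatory gaze.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BlockKind, Direction
from .events import DetectionParams, calibration_errors, detect_trial_events
from .geometry import AngularConvention
from .metrics import METRIC_COLUMNS, compute_trial_metrics, metrics_row, summarize
from .simulate import (
    CohortParams,
    DisplayGeometry,
    draw_participant_effects,
    simulate_calibration_checks,
    simulate_cohort,
)
from .stats import (
    MixedAnovaResults,
    MixedModelResults,
    TestResult,
    compare_blocks,
    compare_groups,
    fit_random_intercept_model,
    mixed_anova,
)

__all__ = [
    "analyze_cohort",
    "calibration_table",
    "stats_report",
    "StatsReport",
    "MIXED_MODEL_RESPONSES",
]

MIXED_MODEL_RESPONSES = {
    "catchup_amplitude": "First catch-up saccade amplitude",
    "catchup_duration_ms": "First catch-up saccade duration",
    "fixation_after_catchup_deviation": "First fixation after catch-up saccade",
    "fixation_at_reach_onset_deviation": "Fixation at reach onset deviation",
}

ANOVA_DVS = [
    "anticipatory_deviation",
    "catchup_amplitude",
    "catchup_duration_ms",
    "fixation_after_catchup_deviation",
    "fixation_at_reach_onset_deviation",
]

KINEMATIC_DVS = ["peak_reach_velocity", "reach_duration", "reach_latency"]


def analyze_cohort(
    params: CohortParams | None = None,
    design_seed: int = 0,
    geometry: DisplayGeometry | None = None,
    detection: DetectionParams | None = None,
    convention: AngularConvention | None = None,
    include_ground_truth: bool = True,
) -> pd.DataFrame:
    """Simulate a cohort and run detection + metrics on every trial.

    Returns the long trial table (one row per trial).  Ground-truth columns
    (``gt_*``) carry the injected values for recovery checks.
    """
    params = params or CohortParams()
    geometry = geometry or DisplayGeometry()
    detection = detection or DetectionParams()
    convention = convention or AngularConvention(geometry.viewing_distance)
    rows = []
    for rec in simulate_cohort(params, design_seed, geometry):
        ev = detect_trial_events(
            rec.gaze,
            rec.hand,
            motion_onset_t=geometry.stationary_duration,
            tone_t=rec.spec.tone_time,
            params=detection,
            convention=convention,
        )
        m = compute_trial_metrics(rec, ev, geometry, detection)
        row = metrics_row(rec, m)
        if include_ground_truth:
            gt = rec.ground_truth
            row.update(
                gt_anticipatory_offset=gt.anticipatory_offset,
                gt_catchup_duration_ms=gt.catchup.duration_ms,
                gt_catchup_planned_ms=gt.catchup_duration_planned_ms,
                gt_peak_velocity=gt.peak_velocity,
                gt_reach_latency=gt.reach_latency,
                gt_corruption=gt.corruption or "none",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def calibration_table(params: CohortParams, design_seed: int = 0) -> pd.DataFrame:
    """Per participant × block calibration-check error summaries."""
    rows = []
    for p in range(params.n_participants):
        group = Direction.RIGHT if p % 2 == 0 else Direction.LEFT
        eff_seed = int(
            np.random.SeedSequence([design_seed, p]).generate_state(2)[1] % (2**31)
        )
        effects = draw_participant_effects(params, np.random.default_rng(eff_seed))
        seg_seed = int(
            np.random.SeedSequence([design_seed, p, 7]).generate_state(1)[0] % (2**31)
        )
        checks = simulate_calibration_checks(effects, params, seg_seed)
        for block, segments in checks.items():
            res = calibration_errors(segments)
            rows.append(
                {
                    "participant": p,
                    "group": group.value,
                    "block": block.value,
                    "displacement_error": res.displacement_error,
                    "absolute_error": res.absolute_error,
                    "passed": res.passed,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StatsReport:
    """Every inferential output of one pipeline run."""

    anovas: dict[str, MixedAnovaResults] = field(default_factory=dict)
    baseline_tests: dict[str, TestResult] = field(default_factory=dict)
    kinematic_tests: dict[str, TestResult] = field(default_factory=dict)
    mixed_models: dict[str, MixedModelResults] = field(default_factory=dict)
    block_means: dict[str, dict[str, float]] = field(default_factory=dict)
    exclusion_fraction: float = float("nan")
    n_participants: int = 0

    def to_dict(self) -> dict:
        def f(x):
            return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)

        out: dict = {
            "n_participants": self.n_participants,
            "exclusion_fraction": f(self.exclusion_fraction),
            "block_means": {
                dv: {k: f(v) for k, v in d.items()} for dv, d in self.block_means.items()
            },
            "anovas": {},
            "baseline_tests": {},
            "kinematic_tests": {},
            "mixed_models": {},
        }
        for name, res in self.anovas.items():
            out["anovas"][name] = {
                e.name: {
                    "F": f(e.F),
                    "df1": f(e.df1),
                    "df2": f(e.df2),
                    "p": f(e.p),
                    "partial_eta_sq": f(e.partial_eta_sq),
                    "gg_epsilon": f(e.gg_epsilon),
                    "corrected": bool(e.corrected),
                }
                for e in res.effects.values()
            }
        for bucket, src in (
            ("baseline_tests", self.baseline_tests),
            ("kinematic_tests", self.kinematic_tests),
        ):
            for name, t in src.items():
                out[bucket][name] = {
                    k: (f(v) if isinstance(v, (int, float)) else v)
                    for k, v in dataclasses.asdict(t).items()
                }
        for name, mm in self.mixed_models.items():
            out["mixed_models"][name] = {
                "robust": mm.robust,
                "random_intercept_sd": f(mm.random_intercept_sd),
                "residual_sd": f(mm.scale),
                "fixed_effects": {
                    k: {
                        "estimate": f(mm.params[k]),
                        "std_error": f(mm.bse[k]),
                        "ci_low": f(mm.ci_low[k]),
                        "ci_high": f(mm.ci_high[k]),
                        "significant": bool(mm.significant[k]),
                    }
                    for k in mm.params.index
                },
            }
        return out

    def summary(self) -> str:
        parts = [
            f"Pipeline stats report — {self.n_participants} participants, "
            f"{self.exclusion_fraction:.2%} of experimental trials excluded",
            "",
        ]
        for name, res in self.anovas.items():
            parts.append(f"[ANOVA] {name}")
            parts.append(res.summary())
            parts.append("")
        for name, t in self.baseline_tests.items():
            parts.append(
                f"[no-bias baseline] {name}: {t.test_used} statistic={t.statistic:.2f}"
                + (f", df={t.df:.0f}" if t.df is not None else "")
                + f", p={t.p:.3f}"
            )
        parts.append("")
        for name, t in self.kinematic_tests.items():
            stat = f"z={t.z:.2f}" if t.z is not None else f"stat={t.statistic:.2f}"
            parts.append(f"[blocks] {name}: {t.test_used} {stat}, p={t.p:.3f}")
        parts.append("")
        for name, mm in self.mixed_models.items():
            parts.append(f"[mixed model] {MIXED_MODEL_RESPONSES.get(name, name)}")
            parts.append(mm.summary())
            parts.append("")
        return "\n".join(parts)


def stats_report(
    trials: pd.DataFrame,
    calib: pd.DataFrame | None = None,
    robust: bool = True,
) -> StatsReport:
    """Run the full inferential battery on a trial table."""
    report = StatsReport()
    report.n_participants = trials["participant"].nunique()

    exp = trials[~trials["is_distractor"]]
    report.exclusion_fraction = float(exp["excluded"].mean()) if len(exp) else float("nan")

    summaries = summarize(trials)
    biased = summaries[summaries["block"].isin(["biased_1", "biased_2"])]
    nobias = summaries[summaries["block"] == "no_bias"]

    for dv in ANOVA_DVS:
        sub = biased.dropna(subset=[dv])
        if sub["participant"].nunique() >= 4:
            report.anovas[dv] = mixed_anova(
                sub, dv=dv, within="block", subject="participant", between="group"
            )
            means = sub.groupby("block")[dv].mean()
            report.block_means[dv] = {b: float(v) for b, v in means.items()}
        g_r = nobias.loc[nobias["group"] == "right", dv].dropna()
        g_l = nobias.loc[nobias["group"] == "left", dv].dropna()
        if len(g_r) >= 2 and len(g_l) >= 2:
            report.baseline_tests[dv] = compare_groups(g_l, g_r)

    if calib is not None and len(calib) and calib["participant"].nunique() >= 4:
        for dv in ("displacement_error", "absolute_error"):
            report.anovas[f"calibration_{dv}"] = mixed_anova(
                calib, dv=dv, within="block", subject="participant", between="group"
            )

    wide = biased.pivot_table(index="participant", columns="block", values=KINEMATIC_DVS)
    for dv in KINEMATIC_DVS:
        if (dv, "biased_1") in wide.columns and (dv, "biased_2") in wide.columns:
            pair = wide[dv].dropna()
            if len(pair) >= 3:
                report.kinematic_tests[dv] = compare_blocks(
                    pair["biased_1"].to_numpy(), pair["biased_2"].to_numpy()
                )
            means = pair.mean()
            report.block_means[dv] = {b: float(v) for b, v in means.items()}

    # trial-level mixed models on the biased blocks, reference levels:
    # biased block 1, rightward bias
    tl = trials[
        (~trials["is_distractor"])
        & (~trials["excluded"])
        & trials["block"].isin(["biased_1", "biased_2"])
    ].copy()
    tl["anticipatory_gaze"] = tl["anticipatory_deviation"]
    tl["biased_block"] = (tl["block"] == "biased_2").astype(float)
    tl["directionality_bias"] = (tl["group"] == "left").astype(float)
    predictors = ["anticipatory_gaze", "biased_block", "directionality_bias"]
    for response in MIXED_MODEL_RESPONSES:
        sub = tl.dropna(subset=[response, "anticipatory_gaze"])
        if sub["participant"].nunique() >= 4:
            report.mixed_models[response] = fit_random_intercept_model(
                sub, response, predictors, robust=robust
            )
    return report
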