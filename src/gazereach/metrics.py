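"""Per-trial dependent variables, exclusion rules and aggregation.

Sign convention for every gaze deviation: positive = ahead of the target's
horizontal midline in the direction of the eventual target movement
(deviation = (gaze_x − target_x) · sign(direction), rightward = +1).

The anticipatory deviation averages gaze over the first 2.5 s of the trial
(all valid samples, saccadic or not; a saccade-free variant that averages
only fixation samples is available).  Reactive deviations are measured
against the target's position at each event's reference time: the fixation
midpoint for the post-catch-up fixation, the reach-onset time for the
reach-onset fixation — the target moves, so the reference must too.

A trial is excluded when the task was executed incorrectly: reach onset
before the tone, grasp landing outside the target's extent, or the target
escaping the screen before contact; equipment failures surface as missing
data.  Timing-distractor trials are never analysed but are not "excluded" —
they are simply not experimental trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Direction, TrialSpec
from .events import (
    DetectionParams,
    EventSet,
    Fixation,
    fixation_after_saccade,
    fixation_at_reach_onset,
)
from .geometry import SampleSeries, speed
from .simulate import DisplayGeometry, TrialRecording

__all__ = [
    "TrialMetrics",
    "anticipatory_deviation",
    "reactive_deviations",
    "reach_kinematics",
    "apply_exclusions",
    "compute_trial_metrics",
    "metrics_row",
    "trial_table",
    "summarize",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "anticipatory_deviation",
    "catchup_amplitude",
    "catchup_duration_ms",
    "fixation_after_catchup_deviation",
    "fixation_at_reach_onset_deviation",
    "peak_reach_velocity",
    "reach_duration",
    "reach_latency",
]


@dataclass
class TrialMetrics:
    anticipatory_deviation: float | None = None
    catchup_amplitude: float | None = None
    catchup_duration_ms: float | None = None
    fixation_after_catchup_deviation: float | None = None
    fixation_at_reach_onset_deviation: float | None = None
    peak_reach_velocity: float | None = None
    reach_duration: float | None = None
    reach_latency: float | None = None
    excluded: bool = False
    exclusion_reason: str = "none"


def anticipatory_deviation(
    gaze: SampleSeries,
    target_center_x: float,
    direction: Direction,
    window: tuple[float, float] = (0.0, 2.5),
    fixations: list[Fixation] | None = None,
) -> float | None:
    """Mean signed gaze deviation over the stationary (anticipatory) window.

    With ``fixations`` given, only samples inside detected fixations count
    (the saccade-free variant); by default every valid sample in the window
    contributes.  None when no valid sample exists.
    """
    x = gaze.channel("x")
    sel = (gaze.t >= window[0]) & (gaze.t < window[1]) & np.isfinite(x)
    if fixations is not None:
        in_fix = np.zeros(gaze.n, dtype=bool)
        for f in fixations:
            in_fix |= (gaze.t >= f.start_t) & (gaze.t <= f.end_t)
        sel &= in_fix
    if not sel.any():
        return None
    return float((x[sel] - target_center_x).mean() * direction.sign)


def _target_x_at(target: SampleSeries, t: float) -> float:
    return float(np.interp(t, target.t, target.channel("x")))


def reactive_deviations(
    events: EventSet,
    target: SampleSeries,
    direction: Direction,
) -> tuple[float | None, float | None]:
    """(post-catch-up fixation deviation, reach-onset fixation deviation).

    Each is signed-ahead relative to the target midline read from the target
    trace at the event's reference time; None where the defining event is
    missing.
    """
    s = direction.sign
    after = None
    if events.first_catchup is not None:
        f = fixation_after_saccade(events.fixations, events.first_catchup)
        if f is not None:
            after = s * (f.centroid_x - _target_x_at(target, f.midpoint_t))
    at_reach = None
    if events.reach_onset_t is not None:
        f = fixation_at_reach_onset(events.fixations, events.reach_onset_t)
        if f is not None:
            at_reach = s * (f.centroid_x - _target_x_at(target, events.reach_onset_t))
    return after, at_reach


def reach_kinematics(
    hand: SampleSeries,
    events: EventSet,
    tone_t: float,
    smoothing_window: int = 5,
) -> tuple[float | None, float | None, float | None]:
    """(peak wrist speed over [onset, contact], contact−onset, onset−tone)."""
    if events.reach_onset_t is None or events.contact_t is None:
        return None, None, None
    sp = speed(hand, ["wrist_x", "wrist_y", "wrist_z"], smoothing_window)
    sel = (sp.t >= events.reach_onset_t) & (sp.t <= events.contact_t)
    vals = sp.channel("speed")[sel]
    peak = float(np.nanmax(vals)) if sel.any() else None
    duration = events.contact_t - events.reach_onset_t
    latency = events.reach_onset_t - tone_t
    return peak, float(duration), float(latency)


def apply_exclusions(
    metrics: TrialMetrics,
    events: EventSet,
    spec: TrialSpec,
    target: SampleSeries,
    geometry: DisplayGeometry,
) -> TrialMetrics:
    """Flag incorrectly executed trials, in the order the rules are stated:
    premature reach, missed grasp, target escape; unmeasurable trials count
    as equipment failures."""
    if events.reach_onset_t is None or events.contact_t is None:
        metrics.excluded = True
        metrics.exclusion_reason = "equipment"
        return metrics
    if events.reach_onset_t < spec.tone_time:
        metrics.excluded = True
        metrics.exclusion_reason = "early_reach"
        return metrics
    target_at_contact = _target_x_at(target, events.contact_t)
    if events.contact_x is not None and abs(events.contact_x - target_at_contact) > (
        geometry.target_width / 2
    ):
        metrics.excluded = True
        metrics.exclusion_reason = "missed_grasp"
        return metrics
    tx = target.channel("x")
    before_contact = target.t <= events.contact_t
    if np.any(np.abs(tx[before_contact]) > geometry.screen_half_width):
        metrics.excluded = True
        metrics.exclusion_reason = "target_escaped"
        return metrics
    if metrics.anticipatory_deviation is None:
        metrics.excluded = True
        metrics.exclusion_reason = "equipment"
    return metrics


def compute_trial_metrics(
    recording: TrialRecording,
    events: EventSet,
    geometry: DisplayGeometry | None = None,
    params: DetectionParams | None = None,
    anticipatory_fixations_only: bool = False,
) -> TrialMetrics:
    """Assemble every dependent variable for one trial and apply exclusions."""
    geometry = geometry or DisplayGeometry()
    params = params or DetectionParams()
    spec = recording.spec
    m = TrialMetrics()
    m.anticipatory_deviation = anticipatory_deviation(
        recording.gaze,
        target_center_x=0.0,
        direction=spec.direction,
        window=(0.0, geometry.stationary_duration),
        fixations=events.fixations if anticipatory_fixations_only else None,
    )
    if events.first_catchup is not None:
        m.catchup_amplitude = events.first_catchup.amplitude
        m.catchup_duration_ms = events.first_catchup.duration_ms
    m.fixation_after_catchup_deviation, m.fixation_at_reach_onset_deviation = (
        reactive_deviations(events, recording.target, spec.direction)
    )
    m.peak_reach_velocity, m.reach_duration, m.reach_latency = reach_kinematics(
        recording.hand, events, spec.tone_time, params.smoothing_window
    )
    return apply_exclusions(m, events, spec, recording.target, geometry)


def metrics_row(recording: TrialRecording, metrics: TrialMetrics) -> dict:
    spec = recording.spec
    return {
        "participant": recording.participant_id,
        "group": recording.group.value,
        "block": spec.block_kind.value,
        "trial": spec.trial_index,
        "direction": spec.direction.value,
        "is_distractor": spec.is_distractor,
        **{c: getattr(metrics, c) for c in METRIC_COLUMNS},
        "excluded": metrics.excluded,
        "exclusion_reason": metrics.exclusion_reason,
    }


def trial_table(rows: list[dict]) -> pd.DataFrame:
    """Long-format trial table (one row per trial, metric columns)."""
    return pd.DataFrame(rows)


def summarize(trials: pd.DataFrame, bias_direction_only: bool = False) -> pd.DataFrame:
    """Participant × block means over included experimental trials.

    Timing distractors and excluded trials never contribute.  With
    ``bias_direction_only`` the averages are restricted to trials moving in
    the block's biased direction (documented alternative; default includes
    all experimental trials under the eventual-direction sign convention).
    """
    sel = (~trials["excluded"]) & (~trials["is_distractor"])
    if bias_direction_only:
        bias_of_group = trials["group"]
        sel &= (trials["block"] == "no_bias") | (trials["direction"] == bias_of_group)
    kept = trials.loc[sel]
    grouped = (
        kept.groupby(["participant", "group", "block"], as_index=False)
        .agg({**{c: "mean" for c in METRIC_COLUMNS}, "trial": "count"})
        .rename(columns={"trial": "n_included"})
    )
    return grouped
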