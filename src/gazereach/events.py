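"""Oculomotor and kinematic event detection.

Saccades: maximal runs of angular speed above 35 deg/s, extended over
adjacent samples whose angular acceleration magnitude exceeds 1000 deg/s²,
with nearby runs merged.  Because the moving-average + central-difference
cascade spreads a motion edge over ``window//2 + 1`` samples on each side,
reported onset/offset times are corrected inward by that operator half-width;
durations of sharp-edged movements are then recovered without bias.

Fixations: classical dispersion-threshold identification (I-DT) — grow a
minimum-duration window (100 ms) while dispersion stays within 1 cm, emit the
maximal window, restart after it.  Dispersion defaults to the sum of the x
and y ranges; max pairwise distance is available as an option.

Reach onset: first upward crossing of 5 cm/s wrist speed that stays above
threshold for at least 50 ms (debounce).  Contact: first sample at which the
index marker is within 0.5 cm of the screen plane.

Masked (NaN) samples split every detector's input into independent segments;
nothing is interpolated across gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .geometry import (
    AngularConvention,
    SampleSeries,
    _central_difference,
    cm_to_deg,
    moving_average,
    resample_to_common,
    speed,
)

__all__ = [
    "DetectionParams",
    "Saccade",
    "Fixation",
    "EventSet",
    "CalibrationResult",
    "detect_saccades",
    "first_catchup_saccade",
    "detect_fixations_idt",
    "fixation_after_saccade",
    "fixation_at_reach_onset",
    "detect_reach_onset",
    "detect_contact",
    "calibration_errors",
    "detect_trial_events",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds (task defaults).

    Angular thresholds are compared in degrees via the small-angle
    convention; everything else is in cm / s.  ``saccade_min_amplitude``
    discards sub-threshold jitter blips (microsaccade-scale artifacts) that a
    pure velocity criterion would otherwise admit under measurement noise.
    """

    saccade_velocity_threshold: float = 35.0  # deg/s
    saccade_accel_threshold: float = 1000.0  # deg/s^2
    saccade_min_delay_after_motion: float = 0.100  # s
    fixation_min_duration: float = 0.100  # s
    fixation_dispersion_max: float = 1.0  # cm
    reach_onset_speed: float = 5.0  # cm/s
    contact_depth: float = 0.5  # cm
    reach_onset_debounce: float = 0.050  # s
    saccade_merge_gap: int = 2  # runs closer than this many samples merge
    saccade_min_amplitude: float = 0.5  # cm
    smoothing_window: int = 5  # samples; differentiation pre-smoothing
    dispersion_metric: str = "range_sum"  # or "max_pairwise"

    def __post_init__(self) -> None:
        positives = (
            self.saccade_velocity_threshold,
            self.saccade_accel_threshold,
            self.saccade_min_delay_after_motion,
            self.fixation_min_duration,
            self.fixation_dispersion_max,
            self.reach_onset_speed,
            self.contact_depth,
        )
        if any(v <= 0 for v in positives):
            raise ConfigurationError("detection thresholds must be positive")
        if self.dispersion_metric not in ("range_sum", "max_pairwise"):
            raise ConfigurationError(f"unknown dispersion metric {self.dispersion_metric!r}")


@dataclass(frozen=True)
class Saccade:
    onset_t: float
    offset_t: float
    amplitude: float  # cm, Euclidean pre-onset → post-offset
    direction: int  # sign of net x displacement

    def __post_init__(self) -> None:
        if self.offset_t <= self.onset_t:
            raise ConfigurationError("saccade offset must follow onset")

    @property
    def duration_ms(self) -> float:
        return (self.offset_t - self.onset_t) * 1000.0

    def amplitude_deg(self, convention: AngularConvention) -> float:
        return cm_to_deg(self.amplitude, convention)


@dataclass(frozen=True)
class Fixation:
    start_t: float
    end_t: float
    centroid_x: float
    centroid_y: float
    dispersion: float

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t

    @property
    def midpoint_t(self) -> float:
        return 0.5 * (self.start_t + self.end_t)

    def contains(self, t: float) -> bool:
        return self.start_t <= t <= self.end_t


@dataclass
class EventSet:
    """Everything detected on one trial."""

    saccades: list[Saccade] = field(default_factory=list)
    fixations: list[Fixation] = field(default_factory=list)
    first_catchup: Saccade | None = None
    reach_onset_t: float | None = None
    contact_t: float | None = None
    contact_x: float | None = None


@dataclass(frozen=True)
class CalibrationResult:
    displacement_error: float  # mean signed horizontal error (cm)
    absolute_error: float  # mean |error| (cm)
    passed: bool


def _valid_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of maximal unmasked runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts, stops))


# ---------------------------------------------------------------------------
# saccades

def detect_saccades(
    gaze: SampleSeries,
    params: DetectionParams = DetectionParams(),
    convention: AngularConvention = AngularConvention(),
) -> list[Saccade]:
    """Velocity + acceleration threshold saccade detection.

    Boundary convention: reported onset/offset are the run edges pulled
    inward by ``window//2 + 1`` samples (the differentiation cascade's edge
    spread), so a movement occupying K inter-sample intervals is reported
    with duration K/rate.
    """
    x = gaze.channel("x")
    y = gaze.channel("y")
    dt = gaze.dt
    edge = params.smoothing_window // 2 + 1
    vel_thr_cm = params.saccade_velocity_threshold * convention.viewing_distance * np.pi / 180.0
    acc_thr_cm = params.saccade_accel_threshold * convention.viewing_distance * np.pi / 180.0

    out: list[Saccade] = []
    for seg_start, seg_stop in _valid_segments(np.isfinite(x) & np.isfinite(y)):
        if seg_stop - seg_start < max(params.smoothing_window, 3):
            continue
        xs = x[seg_start:seg_stop]
        ys = y[seg_start:seg_stop]
        vx = _central_difference(moving_average(xs, params.smoothing_window), dt)
        vy = _central_difference(moving_average(ys, params.smoothing_window), dt)
        sp = np.hypot(vx, vy)
        acc = _central_difference(sp, dt)

        core = sp > vel_thr_cm
        if not core.any():
            continue
        # maximal core runs
        runs = []
        for r0, r1 in _valid_segments(core):
            # extend across adjacent high-|acceleration| samples
            lo = r0
            while lo > 0 and abs(acc[lo - 1]) > acc_thr_cm:
                lo -= 1
            hi = r1
            while hi < sp.size and abs(acc[hi]) > acc_thr_cm:
                hi += 1
            runs.append([lo, hi])
        # merge runs separated by fewer than saccade_merge_gap samples
        merged = [runs[0]]
        for lo, hi in runs[1:]:
            if lo - merged[-1][1] < params.saccade_merge_gap:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])

        for lo, hi in merged:
            on_i = lo + edge
            off_i = hi - 1 - edge
            if off_i <= on_i:  # too short to survive the edge correction
                continue
            pre = max(lo, 0)
            post = min(hi - 1, sp.size - 1)
            dx = xs[post] - xs[pre]
            dy = ys[post] - ys[pre]
            amplitude = float(np.hypot(dx, dy))
            if amplitude < params.saccade_min_amplitude:
                continue
            out.append(
                Saccade(
                    onset_t=float(gaze.t[seg_start + on_i]),
                    offset_t=float(gaze.t[seg_start + off_i]),
                    amplitude=amplitude,
                    direction=int(np.sign(dx)) if dx else 0,
                )
            )
    return out


def first_catchup_saccade(
    saccades: list[Saccade],
    motion_onset_t: float,
    params: DetectionParams = DetectionParams(),
    before_t: float | None = None,
) -> Saccade | None:
    """Earliest saccade starting >= 100 ms after target motion onset.

    ``before_t`` (typically the contact time) bounds the search; None if no
    saccade qualifies.
    """
    cutoff = motion_onset_t + params.saccade_min_delay_after_motion
    qualifying = [
        s
        for s in saccades
        if s.onset_t >= cutoff and (before_t is None or s.onset_t < before_t)
    ]
    return min(qualifying, key=lambda s: s.onset_t) if qualifying else None


# ---------------------------------------------------------------------------
# fixations (I-DT)

def _dispersion(xs, ys, metric: str) -> float:
    if metric == "range_sum":
        return float((xs.max() - xs.min()) + (ys.max() - ys.min()))
    dx = xs[:, None] - xs[None, :]
    dy = ys[:, None] - ys[None, :]
    return float(np.sqrt(dx * dx + dy * dy).max())


def detect_fixations_idt(
    gaze: SampleSeries,
    params: DetectionParams = DetectionParams(),
) -> list[Fixation]:
    """Classical I-DT with incremental window min/max bookkeeping.

    The default dispersion is the Salvucci–Goldberg sum of ranges
    (range_x + range_y); ``max_pairwise`` recomputes pairwise distances per
    window (quadratic, for small windows / cross-checks only).
    """
    x = gaze.channel("x")
    y = gaze.channel("y")
    min_n = int(round(params.fixation_min_duration * gaze.rate)) + 1
    thr = params.fixation_dispersion_max
    out: list[Fixation] = []

    for seg_start, seg_stop in _valid_segments(np.isfinite(x) & np.isfinite(y)):
        xs = x[seg_start:seg_stop]
        ys = y[seg_start:seg_stop]
        m = xs.size
        if m < min_n:
            continue
        if params.dispersion_metric == "range_sum":
            out.extend(
                _idt_range_sum(xs, ys, gaze.t[seg_start:seg_stop], min_n, thr)
            )
        else:
            out.extend(
                _idt_generic(xs, ys, gaze.t[seg_start:seg_stop], min_n, thr, "max_pairwise")
            )
    return out


def _idt_range_sum(xs, ys, ts, min_n: int, thr: float) -> list[Fixation]:
    # the window only ever grows once qualified, so scalar min/max updates
    # keep the scan O(n) outside the sliding (unqualified) phase
    m = xs.size
    out = []
    i = 0
    while i + min_n <= m:
        j = i + min_n
        wx = xs[i:j]
        wy = ys[i:j]
        x_min, x_max = wx.min(), wx.max()
        y_min, y_max = wy.min(), wy.max()
        if (x_max - x_min) + (y_max - y_min) > thr:
            i += 1
            continue
        while j < m:
            nx_min = min(x_min, xs[j])
            nx_max = max(x_max, xs[j])
            ny_min = min(y_min, ys[j])
            ny_max = max(y_max, ys[j])
            if (nx_max - nx_min) + (ny_max - ny_min) > thr:
                break
            x_min, x_max, y_min, y_max = nx_min, nx_max, ny_min, ny_max
            j += 1
        out.append(
            Fixation(
                start_t=float(ts[i]),
                end_t=float(ts[j - 1]),
                centroid_x=float(xs[i:j].mean()),
                centroid_y=float(ys[i:j].mean()),
                dispersion=float((x_max - x_min) + (y_max - y_min)),
            )
        )
        i = j
    return out


def _idt_generic(xs, ys, ts, min_n: int, thr: float, metric: str) -> list[Fixation]:
    m = xs.size
    out = []
    i = 0
    while i + min_n <= m:
        j = i + min_n
        if _dispersion(xs[i:j], ys[i:j], metric) > thr:
            i += 1
            continue
        while j < m and _dispersion(xs[i : j + 1], ys[i : j + 1], metric) <= thr:
            j += 1
        out.append(
            Fixation(
                start_t=float(ts[i]),
                end_t=float(ts[j - 1]),
                centroid_x=float(xs[i:j].mean()),
                centroid_y=float(ys[i:j].mean()),
                dispersion=_dispersion(xs[i:j], ys[i:j], metric),
            )
        )
        i = j
    return out


def fixation_after_saccade(fixations: list[Fixation], saccade: Saccade) -> Fixation | None:
    """Earliest fixation beginning at or after the saccade's offset."""
    after = [f for f in fixations if f.start_t >= saccade.offset_t]
    return min(after, key=lambda f: f.start_t) if after else None


def fixation_at_reach_onset(fixations: list[Fixation], reach_onset_t: float) -> Fixation | None:
    """The fixation containing reach onset, else the latest one ending before it."""
    containing = [f for f in fixations if f.contains(reach_onset_t)]
    if containing:
        return min(containing, key=lambda f: f.start_t)
    preceding = [f for f in fixations if f.end_t <= reach_onset_t]
    return max(preceding, key=lambda f: f.end_t) if preceding else None


# ---------------------------------------------------------------------------
# hand events

def detect_reach_onset(
    wrist_speed: SampleSeries,
    tone_t: float,
    params: DetectionParams = DetectionParams(),
) -> float | None:
    """First sustained upward crossing of the 5 cm/s wrist-speed threshold.

    The search spans the whole trial (not just after the tone) so premature
    reaches surface and can be excluded downstream; a crossing counts only if
    speed stays above threshold for the debounce interval.
    """
    sp = wrist_speed.channel("speed")
    above = np.isfinite(sp) & (sp > params.reach_onset_speed)
    need = int(round(params.reach_onset_debounce * wrist_speed.rate)) + 1
    for r0, r1 in _valid_segments(above):
        if r1 - r0 >= need:
            return float(wrist_speed.t[r0])
    return None


def detect_contact(
    index_depth: SampleSeries,
    params: DetectionParams = DetectionParams(),
    channel: str = "index_z",
) -> float | None:
    """First time the index marker comes within ``contact_depth`` of the screen."""
    z = index_depth.channel(channel)
    hits = np.flatnonzero(np.isfinite(z) & (z <= params.contact_depth))
    return float(index_depth.t[hits[0]]) if hits.size else None


# ---------------------------------------------------------------------------
# calibration checks

def calibration_errors(
    check_segments: list[SampleSeries],
    dot_position: float = 0.0,
    dot_position_y: float = 0.0,
    x_tolerance: float = 0.5,
    y_tolerance: float = 1.0,
) -> CalibrationResult:
    """Signed and absolute horizontal gaze error over fixation-check segments.

    Per segment the error is mean(gaze_x) − dot_x; the displacement error is
    the mean of signed errors, the absolute error the mean of |error|.  The
    pass flag applies the acceptance window (|x| ≤ 0.5 cm, |y| ≤ 1.0 cm).
    """
    if not check_segments:
        raise ConfigurationError("calibration_errors requires at least one segment")
    x_errors, y_errors = [], []
    for seg in check_segments:
        gx = seg.channel("x")
        gx = gx[np.isfinite(gx)]
        if gx.size == 0:
            raise ConfigurationError("calibration segment has no valid samples")
        x_errors.append(gx.mean() - dot_position)
        if "y" in seg.channels:
            gy = seg.channel("y")
            gy = gy[np.isfinite(gy)]
            y_errors.append(gy.mean() - dot_position_y if gy.size else 0.0)
    x_errors = np.asarray(x_errors)
    passed = bool(np.all(np.abs(x_errors) <= x_tolerance)) and (
        not y_errors or bool(np.all(np.abs(np.asarray(y_errors)) <= y_tolerance))
    )
    return CalibrationResult(
        displacement_error=float(x_errors.mean()),
        absolute_error=float(np.abs(x_errors).mean()),
        passed=passed,
    )


# ---------------------------------------------------------------------------
# per-trial orchestration

def detect_trial_events(
    gaze: SampleSeries,
    hand: SampleSeries,
    motion_onset_t: float,
    tone_t: float,
    params: DetectionParams = DetectionParams(),
    convention: AngularConvention = AngularConvention(),
) -> EventSet:
    """Run every detector on one trial's raw streams.

    Wrist speed is computed on the hand stream's native grid; the index
    marker's depth is fused onto the gaze grid (linear interpolation) before
    contact detection, exercising the stream-integration path.
    """
    ev = EventSet()
    ev.saccades = detect_saccades(gaze, params, convention)
    ev.fixations = detect_fixations_idt(gaze, params)

    wrist_speed = speed(hand, ["wrist_x", "wrist_y", "wrist_z"], params.smoothing_window)
    ev.reach_onset_t = detect_reach_onset(wrist_speed, tone_t, params)

    _, hand_on_gaze = resample_to_common(gaze, hand)
    ev.contact_t = detect_contact(hand_on_gaze, params)
    if ev.contact_t is not None:
        ev.contact_x = float(
            np.interp(ev.contact_t, hand_on_gaze.t, hand_on_gaze.channel("index_x"))
        )
    ev.first_catchup = first_catchup_saccade(
        ev.saccades, motion_onset_t, params, before_t=ev.contact_t
    )
    return ev
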