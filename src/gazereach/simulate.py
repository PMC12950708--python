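"""Synthetic reach-to-grasp trials with known (injected) oculomotor events.

The generative model mirrors the task's trial timeline: a target rests at
screen centre for 2.5 s, then translates horizontally at constant speed until
grasped.  Gaze holds an anticipatory fixation offset from the target midline
(signed toward the eventual movement direction), launches a catch-up saccade
a latency after motion onset, and then tracks the target with step-and-hold
fixation plateaus separated by small catch-up transitions.  The hand executes
a minimum-jerk reach whose 5 cm/s wrist-speed crossing and screen contact are
solved to land exactly at the drawn reach latency and duration.

Every injected event (saccade on/offsets, fixation plateaus, reach onset,
contact) is recorded as ground truth so detection can be validated sample-by-
sample.  Saccades are rendered as grid-aligned constant-velocity ramps: sharp
edges make the detected boundaries of the moving-average + central-difference
cascade exactly predictable, so injected durations are recoverable without
bias despite the 4 ms gaze sampling quantisation.

Step-and-hold tracking (rather than continuous smooth pursuit) is a
deliberate idealisation: a 15 cm/s pursuit trace can never satisfy the
1 cm / 100 ms dispersion rule, so the "fixation after the catch-up saccade"
and "fixation at reach onset" would not exist in continuously pursuing
synthetic data.  Plateau loci are anchored at each fixation's midpoint time,
so the injected deviation from the target midline is exactly what the metrics
layer measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.optimize import brentq

from .design import (
    BlockKind,
    Direction,
    SessionDesign,
    TrialSpec,
    generate_session,
)
from .exceptions import ConfigurationError
from .geometry import SampleSeries

__all__ = [
    "DisplayGeometry",
    "CohortParams",
    "ParticipantEffects",
    "GroundTruth",
    "GtSaccade",
    "GtFixation",
    "TrialRecording",
    "minimum_jerk",
    "render_target",
    "simulate_trial",
    "simulate_cohort",
    "simulate_calibration_checks",
    "draw_participant_effects",
    "draw_anticipatory_table",
]

_L, _R = Direction.LEFT, Direction.RIGHT
_NB, _B1, _B2 = BlockKind.NO_BIAS, BlockKind.BIASED_1, BlockKind.BIASED_2


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical task geometry, in cm / s.

    The screen half-width is wider than the task's physical monitor: at the
    cohort's mean contact time the target centre sits ~30 cm from screen
    centre, so a narrower virtual screen would flag typical trials as
    "target escaped".  The escape rule itself is exercised by shrinking this
    value.
    """

    viewing_distance: float = 50.0
    target_width: float = 7.00
    target_height: float = 3.50
    target_speed: float = 15.0
    stationary_duration: float = 2.5
    screen_half_width: float = 36.0

    def __post_init__(self) -> None:
        for name in (
            "viewing_distance",
            "target_width",
            "target_height",
            "target_speed",
            "stationary_duration",
            "screen_half_width",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"DisplayGeometry.{name} must be positive")
        if self.target_width / 2 > self.screen_half_width:
            raise ConfigurationError("target does not fit on screen at trial start")


def _by_block(nb: float, b1: float, b2: float) -> dict[BlockKind, float]:
    return {_NB: nb, _B1: b1, _B2: b2}


def _by_group_block(right: tuple[float, float, float], left: tuple[float, float, float]):
    return {
        (_R, _NB): right[0],
        (_R, _B1): right[1],
        (_R, _B2): right[2],
        (_L, _NB): left[0],
        (_L, _B1): left[1],
        (_L, _B2): left[2],
    }


@dataclass
class CohortParams:
    """Generator truth: the study conditions every block-level metric
    should recover.

    Block-level means are the observed block summaries of the task
    (anticipatory deviations 0.06 / 0.12 / −0.44 cm; catch-up durations
    30.11 / 28.20 ms; peak reach velocities 86.54 / 83.31 cm/s; reach
    duration 0.54 s; latencies 0.97 / 0.96 s).  Between/within SD splits are
    back-solved so participant block means reproduce the corresponding
    summary SDs; both are exposed.  Signed offsets follow the "positive =
    ahead of the target midline in the direction of eventual movement"
    convention throughout.
    """

    n_participants: int = 50

    # anticipatory gaze deviation (cm, signed toward movement direction)
    anticipatory_mean_by_block: dict[BlockKind, float] = field(
        default_factory=lambda: _by_block(0.06, 0.12, -0.44)
    )
    anticipatory_sd_between: dict[BlockKind, float] = field(
        default_factory=lambda: _by_block(0.20, 0.67, 0.70)
    )
    anticipatory_sd_within: float = 0.6

    # oculomotor noise / timing
    fixation_jitter_sd: float = 0.03
    saccade_latency_mean: float = 0.30
    saccade_latency_sd: float = 0.04

    # first catch-up saccade duration (ms)
    catchup_duration_mean_ms: dict[BlockKind, float] = field(
        default_factory=lambda: _by_block(30.11, 30.11, 28.20)
    )
    catchup_duration_sd_between_ms: float = 5.8
    catchup_duration_sd_within_ms: float = 3.0

    # fixation offsets from the target midline (cm, signed-ahead), by (group, block)
    catchup_fixation_offset: dict[tuple[Direction, BlockKind], float] = field(
        default_factory=lambda: _by_group_block((-1.0, 0.18, 0.53), (-1.0, -2.41, -1.74))
    )
    reach_fixation_offset: dict[tuple[Direction, BlockKind], float] = field(
        default_factory=lambda: _by_group_block((-1.4, -1.60, -1.35), (-1.4, -1.17, -0.92))
    )
    fixation_offset_sd_between: float = 0.9
    fixation_offset_sd_within: float = 0.8
    hold_duration: float = 0.28

    # reach kinematics
    peak_reach_velocity: dict[BlockKind, float] = field(
        default_factory=lambda: _by_block(86.54, 86.54, 83.31)
    )
    peak_velocity_sd_between: float = 30.0
    peak_velocity_sd_within: float = 8.0
    reach_duration_mean: dict[BlockKind, float] = field(
        default_factory=lambda: _by_block(0.54, 0.54, 0.54)
    )
    reach_duration_sd_between: float = 0.08
    reach_duration_sd_within: float = 0.05
    reach_latency_mean: dict[BlockKind, float] = field(
        default_factory=lambda: _by_block(0.97, 0.97, 0.96)
    )
    reach_latency_sd_between: float = 0.06
    reach_latency_sd_within: float = 0.03

    # task-execution failures (fraction of trials rendered incorrectly)
    exclusion_rate: float = 0.061

    # calibration-check error structure (cm, horizontal)
    calibration_error_mean: float = -0.03
    calibration_sd_between: float = 0.16
    calibration_sd_check: float = 0.30

    # optional blink gap injector (masked samples); off by default
    blink_rate: float = 0.0
    blink_duration_range: tuple[float, float] = (0.08, 0.20)

    hand_noise_sd: float = 0.02
    gaze_rate: float = 250.0
    hand_rate: float = 100.0

    def validate(self) -> None:
        if self.n_participants < 2 or self.n_participants % 2:
            raise ConfigurationError("n_participants must be even and >= 2")
        sds = [
            self.anticipatory_sd_within,
            self.fixation_jitter_sd,
            self.saccade_latency_sd,
            self.catchup_duration_sd_between_ms,
            self.catchup_duration_sd_within_ms,
            self.fixation_offset_sd_between,
            self.fixation_offset_sd_within,
            self.peak_velocity_sd_between,
            self.peak_velocity_sd_within,
            self.reach_duration_sd_between,
            self.reach_duration_sd_within,
            self.reach_latency_sd_between,
            self.reach_latency_sd_within,
            self.calibration_sd_between,
            self.calibration_sd_check,
            self.hand_noise_sd,
            *self.anticipatory_sd_between.values(),
        ]
        if any(s < 0 for s in sds):
            raise ConfigurationError("standard deviations must be non-negative")
        if not 0 <= self.exclusion_rate < 1:
            raise ConfigurationError("exclusion_rate must be in [0, 1)")
        if self.gaze_rate <= 0 or self.hand_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        for d in (self.catchup_duration_mean_ms, self.reach_duration_mean):
            if any(v <= 0 for v in d.values()):
                raise ConfigurationError("durations must be positive")


@dataclass(frozen=True)
class ParticipantEffects:
    """Additive participant-level random effects around the block means."""

    anticipatory: dict[BlockKind, float]
    catchup_duration_ms: float
    catchup_fixation: float
    reach_fixation: float
    peak_velocity: float
    reach_duration: float
    reach_latency: float
    calibration_offset: float

    @classmethod
    def zero(cls) -> "ParticipantEffects":
        return cls({_NB: 0.0, _B1: 0.0, _B2: 0.0}, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def draw_participant_effects(params: CohortParams, rng: np.random.Generator) -> ParticipantEffects:
    return ParticipantEffects(
        anticipatory={b: rng.normal(0.0, params.anticipatory_sd_between[b]) for b in BlockKind},
        catchup_duration_ms=rng.normal(0.0, params.catchup_duration_sd_between_ms),
        catchup_fixation=rng.normal(0.0, params.fixation_offset_sd_between),
        reach_fixation=rng.normal(0.0, params.fixation_offset_sd_between),
        peak_velocity=rng.normal(0.0, params.peak_velocity_sd_between),
        reach_duration=rng.normal(0.0, params.reach_duration_sd_between),
        reach_latency=rng.normal(0.0, params.reach_latency_sd_between),
        calibration_offset=params.calibration_error_mean
        + rng.normal(0.0, params.calibration_sd_between),
    )


@dataclass(frozen=True)
class GtSaccade:
    onset_t: float
    offset_t: float
    amplitude: float
    duration_ms: float
    is_catchup: bool = False


@dataclass(frozen=True)
class GtFixation:
    start_t: float
    end_t: float
    x: float
    deviation: float  # signed-ahead offset from target midline at the anchor time
    kind: str  # anticipatory | after_catchup | hold


@dataclass
class GroundTruth:
    anticipatory_offset: float  # signed toward eventual movement direction (cm)
    anticipatory_position: float  # absolute screen x of the anticipatory fixation (cm)
    saccades: list[GtSaccade]
    fixations: list[GtFixation]
    reach_onset_t: float
    contact_t: float
    contact_x: float
    peak_velocity: float
    reach_duration: float
    reach_latency: float
    catchup_duration_planned_ms: float  # continuous draw before grid snapping
    corruption: str | None = None

    @property
    def catchup(self) -> GtSaccade:
        return next(s for s in self.saccades if s.is_catchup)


@dataclass
class TrialRecording:
    spec: TrialSpec
    gaze: SampleSeries
    hand: SampleSeries
    target: SampleSeries
    ground_truth: GroundTruth
    participant_id: int = 0
    group: Direction = Direction.RIGHT


# ---------------------------------------------------------------------------
# primitives

def minimum_jerk(tau):
    """Normalized minimum-jerk position profile, 0 → 1 over tau in [0, 1]."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    out = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return float(out) if out.ndim == 0 else out


def _minimum_jerk_inverse(frac: float) -> float:
    if not 0.0 <= frac <= 1.0:
        raise ConfigurationError("minimum-jerk fraction outside [0, 1]")
    if frac in (0.0, 1.0):
        return frac
    return brentq(lambda u: minimum_jerk(u) - frac, 0.0, 1.0, xtol=1e-12)


def render_target(
    t: np.ndarray,
    direction: Direction,
    geometry: DisplayGeometry,
    contact_t: float = math.inf,
    snap_rate: float | None = None,
) -> np.ndarray:
    """Target-centre x: stationary, then a constant-speed ramp frozen at contact.

    With ``snap_rate`` the freeze happens at the last grid sample before
    contact, keeping the sampled trace's per-step speed exactly 0 or the
    target speed (no fractional step at the freeze).
    """
    onset = geometry.stationary_duration
    stop = max(contact_t - onset, 0.0)
    if snap_rate is not None and math.isfinite(stop):
        stop = math.floor(stop * snap_rate) / snap_rate
    tau = np.clip(np.asarray(t, dtype=float) - onset, 0.0, stop)
    return direction.sign * geometry.target_speed * tau


def _target_x_at(t: float, direction: Direction, geometry: DisplayGeometry, contact_t: float) -> float:
    onset = geometry.stationary_duration
    tau = min(max(t - onset, 0.0), max(contact_t - onset, 0.0))
    return direction.sign * geometry.target_speed * tau


def _solve_reach(peak_v: float, duration: float, dz_max: float = 21.6):
    """Fixed-point solve of the minimum-jerk reach geometry.

    Returns (T, D, dz, u_contact, tau_onset): total movement time, path
    length, depth travel of the index marker, and the normalized times at
    which the index marker crosses the 0.5 cm contact plane and wrist speed
    crosses 5 cm/s — so that ``u_contact*T - tau_onset*T == duration`` and
    peak speed ``1.875*D/T == peak_v``.
    """
    T = duration / 0.86
    for _ in range(12):
        D = peak_v * T / 1.875
        dz = min(dz_max, 0.95 * D)
        z_start = 0.4 + dz  # index-marker depth at reach start
        frac = (z_start - 0.5) / dz
        u_c = _minimum_jerk_inverse(frac)
        r = math.sqrt(T / (6.0 * D))
        tau5 = 0.5 * (1.0 - math.sqrt(1.0 - 4.0 * r)) if r < 0.25 else 0.25
        if u_c - tau5 < 0.05:
            raise ConfigurationError("reach geometry degenerate (contact before onset)")
        T = 0.5 * T + 0.5 * duration / (u_c - tau5)
    return T, peak_v * T / 1.875, min(dz_max, 0.95 * peak_v * T / 1.875), u_c, tau5


# ---------------------------------------------------------------------------
# per-trial draws

@dataclass
class _TrialDraws:
    anticipatory: float
    saccade_latency: float
    catchup_duration_s: float
    catchup_offset: float
    reach_offset: float
    peak_velocity: float
    reach_duration: float
    reach_latency: float
    corruption: str | None


def _draw_trial(
    spec: TrialSpec,
    params: CohortParams,
    effects: ParticipantEffects,
    group: Direction,
    rng: np.random.Generator,
) -> _TrialDraws:
    b = spec.block_kind
    clip = lambda v, lo, hi: float(min(max(v, lo), hi))
    corruption = None
    u = rng.uniform()
    if u < params.exclusion_rate:
        corruption = "early_reach" if u < params.exclusion_rate / 2 else "missed_grasp"
    return _TrialDraws(
        anticipatory=params.anticipatory_mean_by_block[b]
        + effects.anticipatory[b]
        + rng.normal(0.0, params.anticipatory_sd_within),
        saccade_latency=clip(
            rng.normal(params.saccade_latency_mean, params.saccade_latency_sd), 0.15, 0.45
        ),
        catchup_duration_s=clip(
            params.catchup_duration_mean_ms[b]
            + effects.catchup_duration_ms
            + rng.normal(0.0, params.catchup_duration_sd_within_ms),
            12.0,
            45.0,
        )
        / 1000.0,
        catchup_offset=params.catchup_fixation_offset[(group, b)]
        + effects.catchup_fixation
        + rng.normal(0.0, params.fixation_offset_sd_within),
        reach_offset=params.reach_fixation_offset[(group, b)]
        + effects.reach_fixation
        + rng.normal(0.0, params.fixation_offset_sd_within),
        peak_velocity=clip(
            params.peak_reach_velocity[b]
            + effects.peak_velocity
            + rng.normal(0.0, params.peak_velocity_sd_within),
            40.0,
            200.0,
        ),
        reach_duration=clip(
            params.reach_duration_mean[b]
            + effects.reach_duration
            + rng.normal(0.0, params.reach_duration_sd_within),
            0.35,
            0.90,
        ),
        reach_latency=clip(
            params.reach_latency_mean[b]
            + effects.reach_latency
            + rng.normal(0.0, params.reach_latency_sd_within),
            0.60,
            1.40,
        ),
        corruption=corruption,
    )


# ---------------------------------------------------------------------------
# rendering

def _transition_samples(amplitude: float) -> int:
    # per-sample step kept > 1.05 cm so I-DT windows never capture
    # transition samples; bounded for sane speeds
    return int(min(max(round(amplitude / 1.5), 2), 5))


_EDGE_STEP = 1.2  # cm; first/last saccade step, beyond the I-DT capture radius


def _saccade_amp_min(k: int) -> float:
    # sharp edge steps plus detectable middle steps
    return 2 * _EDGE_STEP + max(k - 2, 0) * 0.15


def _saccade_interior(a: float, p: float, k: int) -> np.ndarray:
    """Interior sample positions of a k-interval saccade from a to p.

    First and last steps are ``_EDGE_STEP`` (so neither neighbouring I-DT
    window can capture a saccade sample); the middle advances uniformly.
    """
    if k == 2:
        return np.array([(a + p) / 2.0])
    amp = p - a
    e = math.copysign(_EDGE_STEP, amp)
    inner = a + e + (amp - 2 * e) * np.arange(k - 2) / (k - 2)
    return np.append(inner, p - e)


def _render_trial(
    spec: TrialSpec,
    draws: _TrialDraws,
    params: CohortParams,
    geometry: DisplayGeometry,
    rng: np.random.Generator,
    participant_id: int,
    group: Direction,
) -> TrialRecording:
    s = spec.direction.sign
    dt = 1.0 / params.gaze_rate
    motion = geometry.stationary_duration
    tone = spec.tone_time

    # ---- reach timing ------------------------------------------------------
    latency = -0.25 if draws.corruption == "early_reach" else draws.reach_latency
    T, D, dz, u_c, tau5 = _solve_reach(draws.peak_velocity, draws.reach_duration)
    t0 = tone + latency - tau5 * T
    contact = t0 + u_c * T  # == tone + latency + reach_duration
    reach_onset = tone + latency
    end_t = contact + 2.0  # target lingers 2 s after the grasp

    lateral_miss = s * 4.6 if draws.corruption == "missed_grasp" else 0.0
    x_contact = _target_x_at(contact, spec.direction, geometry, contact) + lateral_miss

    # ---- gaze --------------------------------------------------------------
    n = int(round(end_t * params.gaze_rate)) + 1
    tg = np.arange(n) * dt
    a = s * draws.anticipatory
    x = np.full(n, a)

    xt = lambda tt: _target_x_at(tt, spec.direction, geometry, contact)

    i_s = int(round((motion + draws.saccade_latency) * params.gaze_rate))
    K = int(min(max(round(draws.catchup_duration_s / dt), 3), 12))
    hold_n = int(round(params.hold_duration * params.gaze_rate))

    saccades: list[GtSaccade] = []
    fixations: list[GtFixation] = [GtFixation(0.0, tg[i_s], a, draws.anticipatory, "anticipatory")]

    # first hold midpoint sets the catch-up landing position
    first_start = i_s + K
    first_mid = (first_start * dt + min(first_start * dt + params.hold_duration, contact)) / 2.0
    pos0 = xt(first_mid) + s * draws.catchup_offset
    # detectability floor: edge steps must clear the I-DT capture radius and
    # middle steps the velocity threshold (see module docstring)
    amp_min = _saccade_amp_min(K)
    if s * (pos0 - a) < amp_min:
        pos0 = a + s * amp_min

    x[i_s + 1 : i_s + K] = _saccade_interior(a, pos0, K)
    saccades.append(
        GtSaccade(tg[i_s], tg[i_s + K], abs(pos0 - a), K * dt * 1000.0, is_catchup=True)
    )

    # step-and-hold tracking plateaus
    start = first_start
    pos = pos0
    k = 0
    while True:
        planned_end = start + hold_n
        # will the next plateau begin past contact?  then this hold runs out
        final = (planned_end + 5) * dt + 0.06 >= contact or planned_end + 8 >= n
        end = n - 1 if final else planned_end
        mid = (start * dt + min(planned_end * dt, contact)) / 2.0
        off = draws.catchup_offset if k == 0 else draws.reach_offset
        dev = s * (pos - xt(mid))
        x[start : end + 1] = pos
        fixations.append(
            GtFixation(tg[start], tg[end], pos, dev, "after_catchup" if k == 0 else "hold")
        )
        if final:
            break
        # transition saccade to the next plateau
        nxt_mid_est = (end + 3) * dt + params.hold_duration / 2.0
        nxt = xt(min(nxt_mid_est, contact)) + s * draws.reach_offset
        if s * (nxt - pos) < 2.2:
            nxt = pos + s * 2.2
        kt = _transition_samples(abs(nxt - pos))
        nxt_start = end + kt
        mid2 = (nxt_start * dt + min(nxt_start * dt + params.hold_duration, contact)) / 2.0
        nxt = xt(min(mid2, contact)) + s * draws.reach_offset
        if s * (nxt - pos) < max(1.1 * kt, _saccade_amp_min(kt)):
            nxt = pos + s * max(1.1 * kt, _saccade_amp_min(kt))
        x[end + 1 : end + kt] = _saccade_interior(pos, nxt, kt)
        saccades.append(GtSaccade(tg[end], tg[nxt_start], abs(nxt - pos), kt * dt * 1000.0))
        start, pos, k = nxt_start, nxt, k + 1

    y = np.zeros(n)
    if params.fixation_jitter_sd > 0:
        x = x + rng.normal(0.0, params.fixation_jitter_sd, n)
        y = y + rng.normal(0.0, params.fixation_jitter_sd, n)
    if params.blink_rate > 0:
        n_blinks = rng.poisson(params.blink_rate * end_t)
        lo, hi = params.blink_duration_range
        for _ in range(n_blinks):
            b0 = rng.uniform(0.0, end_t)
            b1 = b0 + rng.uniform(lo, hi)
            mask = (tg >= b0) & (tg <= b1)
            x[mask] = np.nan
            y[mask] = np.nan

    gaze = SampleSeries(tg, {"x": x, "y": y}, params.gaze_rate, _validated=True)

    # ---- target ------------------------------------------------------------
    target_x = render_target(tg, spec.direction, geometry, contact, snap_rate=params.gaze_rate)
    target = SampleSeries(tg, {"x": target_x}, params.gaze_rate, _validated=True)

    # ---- hand --------------------------------------------------------------
    dth = 1.0 / params.hand_rate
    nh = int(round(end_t * params.hand_rate)) + 1
    th = np.arange(nh) * dth
    index_end = np.array([x_contact, 0.0, 0.4])
    wrist_end = index_end + np.array([0.0, -2.0, 8.0])
    lateral = math.sqrt(max(D**2 - dz**2, 0.0))
    wrist_start = wrist_end + np.array([0.0, -lateral, dz])
    u = np.clip((th - t0) / T, 0.0, 1.0)
    frac = minimum_jerk(u)
    wrist = wrist_start[None, :] + (wrist_end - wrist_start)[None, :] * frac[:, None]
    index = wrist + np.array([0.0, 2.0, -8.0])
    thumb = wrist + np.array([0.0, -2.0, -8.0])
    channels = {}
    for name, arr in (("wrist", wrist), ("index", index), ("thumb", thumb)):
        for ax, col in zip("xyz", arr.T):
            channels[f"{name}_{ax}"] = (
                col + rng.normal(0.0, params.hand_noise_sd, nh)
                if params.hand_noise_sd > 0
                else col.copy()
            )
    hand = SampleSeries(th, channels, params.hand_rate, _validated=True)

    gt = GroundTruth(
        anticipatory_offset=draws.anticipatory,
        anticipatory_position=a,
        saccades=saccades,
        fixations=fixations,
        reach_onset_t=reach_onset,
        contact_t=contact,
        contact_x=x_contact,
        peak_velocity=1.875 * D / T,
        reach_duration=draws.reach_duration,
        reach_latency=latency,
        catchup_duration_planned_ms=draws.catchup_duration_s * 1000.0,
        corruption=draws.corruption,
    )
    return TrialRecording(spec, gaze, hand, target, gt, participant_id, group)


def simulate_trial(
    spec: TrialSpec,
    params: CohortParams | None = None,
    geometry: DisplayGeometry | None = None,
    seed: int = 0,
    effects: ParticipantEffects | None = None,
    group: Direction | None = None,
    participant_id: int = 0,
) -> TrialRecording:
    """Render one trial; deterministic given ``seed`` (and effects)."""
    params = params or CohortParams()
    params.validate()
    geometry = geometry or DisplayGeometry()
    effects = effects or ParticipantEffects.zero()
    group = group or spec.bias_direction or Direction.RIGHT
    rng = np.random.default_rng(seed)
    draws = _draw_trial(spec, params, effects, group, rng)
    return _render_trial(spec, draws, params, geometry, rng, participant_id, group)


def _participant_seeds(design_seed: int, participant: int, n: int) -> np.ndarray:
    return np.random.SeedSequence([design_seed, participant]).generate_state(n) % (2**31)


def simulate_cohort(
    params: CohortParams | None = None,
    design_seed: int = 0,
    geometry: DisplayGeometry | None = None,
) -> Iterator[TrialRecording]:
    """Lazily yield every trial of a two-group cohort.

    Participants alternate between the rightward- and leftward-bias groups
    (even ids rightward), each with their own pseudorandomized session and
    participant-level random effects.  A generator keeps memory flat: a full
    50-participant cohort is ~500 MB if materialised.
    """
    params = params or CohortParams()
    params.validate()
    geometry = geometry or DisplayGeometry()
    for p in range(params.n_participants):
        group = Direction.RIGHT if p % 2 == 0 else Direction.LEFT
        state = _participant_seeds(design_seed, p, 2 + 96)
        design = generate_session(group, int(state[0]))
        effects = draw_participant_effects(params, np.random.default_rng(int(state[1])))
        for i, spec in enumerate(design.all_trials()):
            rng = np.random.default_rng(int(state[2 + i]))
            draws = _draw_trial(spec, params, effects, group, rng)
            yield _render_trial(spec, draws, params, geometry, rng, p, group)


def simulate_calibration_checks(
    effects: ParticipantEffects,
    params: CohortParams,
    seed: int,
    segment_duration: float = 0.5,
) -> dict[BlockKind, list[SampleSeries]]:
    """Two fixation-check segments per block: gaze staring at the centre dot.

    Each check's true error is the participant's calibration offset plus
    per-check noise; segments carry sample jitter on top.
    """
    rng = np.random.default_rng(seed)
    n = int(round(segment_duration * params.gaze_rate)) + 1
    t = np.arange(n) / params.gaze_rate
    out: dict[BlockKind, list[SampleSeries]] = {}
    for b in BlockKind:
        segs = []
        for _ in range(2):
            err = effects.calibration_offset + rng.normal(0.0, params.calibration_sd_check)
            x = err + rng.normal(0.0, params.fixation_jitter_sd, n)
            y = rng.normal(0.0, params.fixation_jitter_sd, n)
            segs.append(SampleSeries(t, {"x": x, "y": y}, params.gaze_rate, _validated=True))
        out[b] = segs
    return out


def draw_anticipatory_table(
    params: CohortParams,
    seed: int,
    blocks: tuple[BlockKind, ...] = (_B1, _B2),
    n_trials: int = 24,
):
    """Trial-level anticipatory deviations drawn straight from the generative
    distributions (no rendering) — the injected truth that a full pipeline
    pass recovers up to jitter-averaging noise.  Used for replication
    studies where rendering every sample would be waste.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for p in range(params.n_participants):
        group = Direction.RIGHT if p % 2 == 0 else Direction.LEFT
        for b in blocks:
            eff = rng.normal(0.0, params.anticipatory_sd_between[b])
            vals = (
                params.anticipatory_mean_by_block[b]
                + eff
                + rng.normal(0.0, params.anticipatory_sd_within, n_trials)
            )
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "participant": p,
                        "group": group.value,
                        "block": b.value,
                        "trial": i,
                        "anticipatory_deviation": v,
                    }
                )
    return pd.DataFrame(rows)
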