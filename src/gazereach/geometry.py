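"""Units, coordinate conventions, stream fusion and differentiation.

Everything downstream works in a screen-centered frame: x positive rightward,
y positive upward, units of cm on the screen plane; hand channels add a z axis
(cm, distance from the screen plane, positive toward the observer).  Angular
quantities use the small-angle convention ``deg = (cm / d) * 180 / pi`` at the
viewing distance ``d`` — the convention under which a 7.00 cm extent at 50 cm
is 8.02 deg and 15 cm/s is 17.19 deg/s, i.e. the same arithmetic the display
geometry of the task was specified in.  Detection happens in cm; conversion to
degrees is applied only where a threshold is expressed in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "AngularConvention",
    "SampleSeries",
    "cm_to_deg",
    "deg_to_cm",
    "moving_average",
    "velocity",
    "speed",
    "resample_to_common",
]


@dataclass(frozen=True)
class AngularConvention:
    """Small-angle visual-angle convention at a fixed viewing distance (cm)."""

    viewing_distance: float = 50.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.viewing_distance) or self.viewing_distance <= 0:
            raise ConfigurationError(
                f"viewing_distance must be positive and finite, got {self.viewing_distance!r}"
            )


def cm_to_deg(extent_cm, convention: AngularConvention = AngularConvention()):
    """Convert an on-screen extent (or speed) in cm to visual degrees.

    Small-angle: ``deg = (cm / viewing_distance) * 180 / pi``.  Works on
    scalars and arrays; the inverse is :func:`deg_to_cm`.
    """
    extent_cm = np.asarray(extent_cm, dtype=float)
    if not np.all(np.isfinite(extent_cm)):
        raise ConfigurationError("cm_to_deg requires finite input")
    out = extent_cm / convention.viewing_distance * (180.0 / np.pi)
    return float(out) if out.ndim == 0 else out


def deg_to_cm(extent_deg, convention: AngularConvention = AngularConvention()):
    """Inverse of :func:`cm_to_deg` (exact round-trip to machine precision)."""
    extent_deg = np.asarray(extent_deg, dtype=float)
    if not np.all(np.isfinite(extent_deg)):
        raise ConfigurationError("deg_to_cm requires finite input")
    out = extent_deg * convention.viewing_distance * (np.pi / 180.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class SampleSeries:
    """Uniformly sampled, named position traces.

    ``t`` is strictly increasing with constant step ``1/rate``; ``channels``
    maps channel names to float arrays of the same length.  NaN values mark
    masked samples (blinks / dropouts).
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    rate: float
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self._validated:
            return
        if self.t.ndim != 1 or self.t.size < 1:
            raise ConfigurationError("SampleSeries.t must be a non-empty 1-D array")
        if self.rate <= 0:
            raise ConfigurationError("SampleSeries.rate must be positive")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ConfigurationError("SampleSeries.t must be strictly increasing")
            step = 1.0 / self.rate
            if not np.allclose(dt, step, rtol=1e-6, atol=1e-9):
                raise ConfigurationError(
                    f"SampleSeries.t step does not match rate {self.rate} Hz"
                )
        for name, v in self.channels.items():
            if v.shape != self.t.shape:
                raise ConfigurationError(f"channel {name!r} length mismatch with t")
        self._validated = True

    @property
    def n(self) -> int:
        return int(self.t.size)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def with_channels(self, channels: dict[str, np.ndarray]) -> "SampleSeries":
        return SampleSeries(self.t, channels, self.rate, _validated=True)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking (one-sided) windows at the edges.

    ``window`` must be odd.  NaNs propagate to every output sample whose
    window touches them (callers split masked segments first).
    """
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("smoothing window must be a positive odd integer")
    if window > x.size:
        raise ConfigurationError(
            f"smoothing window {window} exceeds series length {x.size}"
        )
    if window == 1:
        return x.copy()
    h = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _central_difference(x: np.ndarray, dt: float) -> np.ndarray:
    """Two-point central difference, one-sided at the endpoints."""
    v = np.empty_like(x)
    if x.size == 1:
        v[0] = 0.0
        return v
    v[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    v[0] = (x[1] - x[0]) / dt
    v[-1] = (x[-1] - x[-2]) / dt
    return v


def velocity(series: SampleSeries, channel: str, smoothing_window: int = 5) -> SampleSeries:
    """Signed rate of change of one channel (units/s).

    The trace is smoothed with a centered ``smoothing_window``-sample moving
    average (default 5 samples = 20 ms at 250 Hz) and differentiated with a
    two-point central difference; endpoints use one-sided differences.
    Apply twice to obtain acceleration.
    """
    if series.n < 3:
        raise ConfigurationError("velocity requires at least 3 samples")
    smoothed = moving_average(series.channel(channel), smoothing_window)
    v = _central_difference(smoothed, series.dt)
    return series.with_channels({channel: v})


def speed(series: SampleSeries, channels: list[str], smoothing_window: int = 5) -> SampleSeries:
    """Euclidean norm of per-channel velocities: a ``speed`` trace in units/s."""
    if series.n < 3:
        raise ConfigurationError("speed requires at least 3 samples")
    comps = []
    for name in channels:
        smoothed = moving_average(series.channel(name), smoothing_window)
        comps.append(_central_difference(smoothed, series.dt))
    sp = np.sqrt(np.sum(np.square(np.stack(comps)), axis=0))
    return series.with_channels({"speed": sp})


def resample_to_common(gaze: SampleSeries, hand: SampleSeries) -> tuple[SampleSeries, SampleSeries]:
    """Put gaze and hand streams on a shared grid (the gaze time base).

    Hand channels are linearly interpolated onto the gaze samples lying inside
    the hand stream's span; gaze samples outside that span are dropped, so no
    extrapolation ever happens.  Raises if the spans do not overlap.
    """
    t0 = max(gaze.t[0], hand.t[0])
    t1 = min(gaze.t[-1], hand.t[-1])
    if t1 <= t0:
        raise ConfigurationError("gaze and hand spans do not overlap")
    keep = (gaze.t >= t0 - 1e-12) & (gaze.t <= t1 + 1e-12)
    tg = gaze.t[keep]
    gaze_out = SampleSeries(
        tg, {k: v[keep] for k, v in gaze.channels.items()}, gaze.rate, _validated=True
    )
    hand_out = SampleSeries(
        tg,
        {k: np.interp(tg, hand.t, v) for k, v in hand.channels.items()},
        gaze.rate,
        _validated=True,
    )
    return gaze_out, hand_out
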