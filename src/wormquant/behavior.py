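"""Posture- and velocity-trace scoring of worm behavioral endpoints.

Turns per-worm kinematic traces into the categorical and rate endpoints used
to compare strains: tap-evoked reversals, swimming-induced paralysis (SWIP),
thrash frequency over the swim assay, and body-bend counts for the basal
slowing response.

A "C-shaped bend" is operationalized as the midbody bend angle crossing a
configurable threshold (default 45 deg) with hysteresis (default 10 deg) and
alternating sides; one thrash is one full left-right swimming cycle, i.e.
two alternating bend events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .errors import CoverageError, ParameterError

__all__ = [
    "PostureTrace",
    "VelocityTrace",
    "BendEvent",
    "ReversalCall",
    "ThrashEstimate",
    "detect_bends",
    "call_paralysis",
    "thrash_frequency",
    "count_body_bends",
    "call_reversal",
]


def _check_uniform(time: np.ndarray, what: str) -> float:
    if time.size < 2:
        raise ParameterError(f"{what} needs at least two samples")
    dt = np.diff(time)
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise ParameterError(f"{what} time must be strictly increasing")
    if np.max(np.abs(dt - dt_med)) > 0.01 * dt_med:
        raise ParameterError(f"{what} sampling jitter exceeds 1% of the interval")
    return 1.0 / dt_med


@dataclass
class PostureTrace:
    """Uniformly sampled signed midbody bend angle, in degrees."""

    time: np.ndarray
    bend_angle: np.ndarray
    sample_rate: float = 0.0  # inferred from `time` when left at 0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.bend_angle = np.asarray(self.bend_angle, dtype=float)
        if self.time.shape != self.bend_angle.shape:
            raise ParameterError("time and bend_angle must share shape")
        if not np.all(np.isfinite(self.bend_angle)):
            raise ParameterError("bend_angle must be finite")
        inferred = _check_uniform(self.time, "posture trace")
        if self.sample_rate == 0.0:
            self.sample_rate = inferred

    def covers(self, start: float, end: float) -> bool:
        tol = 0.5 / self.sample_rate
        return self.time[0] <= start + tol and self.time[-1] >= end - tol


@dataclass
class VelocityTrace:
    """Signed crawling speed in body-lengths/s; NaN marks untracked gaps."""

    time: np.ndarray
    signed_speed: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signed_speed = np.asarray(self.signed_speed, dtype=float)
        if self.time.shape != self.signed_speed.shape:
            raise ParameterError("time and signed_speed must share shape")
        self.sample_rate = _check_uniform(self.time, "velocity trace")


class BendEvent(NamedTuple):
    time: float
    side: int  # +1 dorsal-wards, -1 ventral-wards (sign of the crossing)


@dataclass
class ReversalCall:
    """Outcome of one tap for one worm.

    ``reversed`` is None when the worm was untracked during the scoring
    window; untracked worms are excluded from population denominators.
    """

    worm_id: object
    tap_index: int
    tracked: bool
    reversed: Optional[bool]
    latency: Optional[float] = None

    def __post_init__(self):
        if (self.latency is not None) != bool(self.reversed):
            raise ParameterError("latency must be present iff the worm reversed")


class ThrashEstimate(NamedTuple):
    frequency_hz: float
    n_events: int
    interval: tuple[float, float]


def detect_bends(
    trace: PostureTrace, theta_c: float = 45.0, hysteresis: float = 10.0
) -> list[BendEvent]:
    """Side-alternating threshold crossings of the bend angle.

    An event fires when |bend_angle| crosses above ``theta_c`` on the side
    opposite the previous event; after each event the angle must drop below
    ``theta_c - hysteresis`` in magnitude before another event can fire.
    Events are strictly time-ordered and alternate sides.
    """
    if not theta_c > hysteresis > 0:
        raise ParameterError("require theta_c > hysteresis > 0")
    events: list[BendEvent] = []
    armed = True
    last_side = 0
    lower = theta_c - hysteresis
    for t, a in zip(trace.time, trace.bend_angle):
        if armed:
            side = 1 if a > theta_c else (-1 if a < -theta_c else 0)
            if side != 0 and side != last_side:
                events.append(BendEvent(float(t), side))
                last_side = side
                armed = False
        elif abs(a) < lower:
            armed = True
    return events


def call_paralysis(
    trace: PostureTrace,
    assay_time: float = 600.0,
    quiet_window: float = 5.0,
    theta_c: float = 45.0,
    hysteresis: float = 10.0,
) -> bool:
    """Paralysis at the assay time point: no bend events in the last window.

    The worm is called paralyzed when :func:`detect_bends` yields zero events
    inside [assay_time - quiet_window, assay_time] (default: no C-shaped
    bends in the 5 s preceding the 10-minute mark).
    """
    start = assay_time - quiet_window
    if not trace.covers(start, assay_time):
        raise CoverageError(
            f"trace does not cover the paralysis window [{start}, {assay_time}] s"
        )
    events = detect_bends(trace, theta_c=theta_c, hysteresis=hysteresis)
    return not any(start <= e.time <= assay_time for e in events)


def thrash_frequency(
    trace: PostureTrace,
    interval: tuple[float, float] = (0.0, 660.0),
    theta_c: float = 45.0,
    hysteresis: float = 10.0,
) -> ThrashEstimate:
    """Swimming frequency as alternating bend events per full cycle.

    One thrash = one full left-right cycle = two alternating bend events, so
    frequency = events / (2 * interval length).
    """
    start, end = interval
    if end <= start:
        raise ParameterError("interval must have positive length")
    if not trace.covers(start, end):
        raise CoverageError(f"trace does not cover the interval [{start}, {end}] s")
    events = detect_bends(trace, theta_c=theta_c, hysteresis=hysteresis)
    n = sum(1 for e in events if start <= e.time <= end)
    return ThrashEstimate(n / (2.0 * (end - start)), n, (float(start), float(end)))


def count_body_bends(
    trace: PostureTrace,
    interval: tuple[float, float] = (60.0, 120.0),
    theta_c: float = 45.0,
    hysteresis: float = 10.0,
) -> int:
    """Bend-event count over the scoring interval (basal slowing endpoint)."""
    start, end = interval
    if not trace.covers(start, end):
        raise CoverageError(f"trace does not cover the interval [{start}, {end}] s")
    events = detect_bends(trace, theta_c=theta_c, hysteresis=hysteresis)
    return sum(1 for e in events if start <= e.time <= end)


def call_reversal(
    velocity: VelocityTrace,
    tap_time: float,
    window: float = 1.0,
    min_back_duration: float = 0.2,
    back_speed_threshold: float = 0.05,
    worm_id: object = None,
    tap_index: int = 0,
) -> ReversalCall:
    """Tap-evoked reversal: sustained backward motion after the tap.

    The worm reversed iff signed speed stays below ``-back_speed_threshold``
    for at least ``min_back_duration`` within [tap_time, tap_time + window];
    latency is the onset of the first such run relative to the tap.  Any
    untracked gap (NaN speed) overlapping the window yields an untracked
    call, excluded from population denominators.
    """
    t0, t1 = tap_time, tap_time + window
    if velocity.time[0] > t0 or velocity.time[-1] < t1:
        raise ParameterError("tap window extends beyond the velocity trace")
    mask = (velocity.time >= t0) & (velocity.time <= t1)
    speed = velocity.signed_speed[mask]
    times = velocity.time[mask]
    if np.any(np.isnan(speed)):
        return ReversalCall(worm_id, tap_index, tracked=False, reversed=None)

    dt = 1.0 / velocity.sample_rate
    backward = speed < -back_speed_threshold
    run_len = 0
    for i, b in enumerate(backward):
        run_len = run_len + 1 if b else 0
        if run_len * dt >= min_back_duration:
            onset = times[i - run_len + 1]
            return ReversalCall(
                worm_id, tap_index, tracked=True, reversed=True,
                latency=float(onset - tap_time),
            )
    return ReversalCall(worm_id, tap_index, tracked=True, reversed=False)
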