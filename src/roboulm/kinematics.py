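"""Trapezoidal motion-profile kinematics for translation stages and the robot.

A move of signed ``distance`` is executed with constant acceleration ``accel``
up to at most ``vmax``, an optional constant-speed cruise, and a symmetric
deceleration to rest.  When the commanded distance is shorter than
``vmax**2 / accel`` the profile is triangular: the peak speed
``sqrt(accel * |distance|)`` is reached at mid-move and never cruises.

All distances are millimetres, times seconds, speeds mm/s, accelerations
mm/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrapezoidSegment",
    "MotionProfile",
    "trapezoid_displacement",
    "min_distance_to_reach_vmax",
    "build_protocol",
    "STAGE_MAX_SPEED_MM_S",
    "STAGE_ACCEL_MM_S2",
]

#: Maximum speed of a single motorised translation stage (mm/s).
SINGLE_STAGE_MAX_SPEED_MM_S = 2.6
#: Two stages stacked in series and driven together double the reachable speed.
STAGE_MAX_SPEED_MM_S = 2 * SINGLE_STAGE_MAX_SPEED_MM_S
#: Fixed acceleration/deceleration of the stage protocol (mm/s^2).
STAGE_ACCEL_MM_S2 = 3.0


@dataclass(frozen=True)
class TrapezoidSegment:
    """One straight trapezoidal move starting from rest and ending at rest."""

    start_time: float
    distance: float
    accel: float
    vmax: float

    def __post_init__(self) -> None:
        if self.accel <= 0:
            raise ValueError(f"accel must be > 0, got {self.accel}")
        if self.vmax <= 0:
            raise ValueError(f"vmax must be > 0, got {self.vmax}")

    @property
    def peak_speed(self) -> float:
        """Largest speed attained: min(vmax, sqrt(accel * |distance|))."""
        return min(self.vmax, float(np.sqrt(self.accel * abs(self.distance))))

    @property
    def duration(self) -> float:
        d = abs(self.distance)
        if d == 0.0:
            return 0.0
        d_ramp = self.vmax**2 / self.accel  # accel + decel distance at full speed
        if d <= d_ramp:
            # triangular: accelerate to sqrt(a d), decelerate
            return 2.0 * float(np.sqrt(d / self.accel))
        t_ramp = self.vmax / self.accel
        return 2.0 * t_ramp + (d - d_ramp) / self.vmax

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def displacement(self, t):
        """Signed displacement along the segment at time ``t`` (vectorised)."""
        t = np.asarray(t, dtype=float)
        tau = np.clip(t - self.start_time, 0.0, self.duration)
        d = abs(self.distance)
        if d == 0.0:
            out = np.zeros_like(tau)
            return out if out.ndim else float(out)
        a = self.accel
        vpk = self.peak_speed
        t_acc = vpk / a
        t_total = self.duration
        t_dec = t_total - t_acc  # decel start (equals t_acc when triangular)

        out = np.empty_like(tau)
        ramp_up = tau <= t_acc
        ramp_down = tau >= t_dec
        cruise = ~ramp_up & ~ramp_down
        out[ramp_up] = 0.5 * a * tau[ramp_up] ** 2
        out[cruise] = 0.5 * a * t_acc**2 + vpk * (tau[cruise] - t_acc)
        td = t_total - tau[ramp_down]
        out[ramp_down] = d - 0.5 * a * td**2
        out = np.sign(self.distance) * out
        return out if out.ndim else float(out)

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        tau = t - self.start_time
        d = abs(self.distance)
        if d == 0.0:
            out = np.zeros_like(tau)
            return out if out.ndim else float(out)
        a = self.accel
        vpk = self.peak_speed
        t_acc = vpk / a
        t_total = self.duration
        out = np.zeros_like(tau)
        inside = (tau >= 0) & (tau <= t_total)
        v = np.minimum.reduce([a * tau, np.full_like(tau, vpk), a * (t_total - tau)])
        out[inside] = v[inside]
        out = np.sign(self.distance) * out
        return out if out.ndim else float(out)


def trapezoid_displacement(t, seg: TrapezoidSegment):
    """Signed displacement of ``seg`` at time ``t`` (>= seg.start_time)."""
    return seg.displacement(t)


def min_distance_to_reach_vmax(vmax: float, accel: float) -> float:
    """Shortest commanded move whose trapezoidal profile just attains ``vmax``.

    Accelerating over ``vmax**2 / (2 accel)`` and immediately decelerating
    gives ``vmax**2 / accel``; any shorter move peaks below ``vmax``.
    """
    if vmax <= 0 or accel <= 0:
        raise ValueError("vmax and accel must be > 0")
    return vmax**2 / accel


@dataclass(frozen=True)
class MotionProfile:
    """Sequence of trapezoidal segments along a single probe-frame direction.

    ``axis_direction`` is a unit 3-vector in the probe frame
    (x = lateral, y = elevational, z = depth).
    """

    segments: tuple[TrapezoidSegment, ...]
    axis_direction: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0])
    )

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.start_time < a.end_time - 1e-12:
                raise ValueError("segments overlap in time")
        u = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(u)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis_direction must be a nonzero vector")
        object.__setattr__(self, "axis_direction", u / n)

    @property
    def end_time(self) -> float:
        return max((s.end_time for s in self.segments), default=0.0)

    @property
    def start_time(self) -> float:
        return min((s.start_time for s in self.segments), default=0.0)

    def displacement(self, t):
        """Scalar displacement along the axis at time ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for seg in self.segments:
            out = out + seg.displacement(t)
        return out if out.ndim else float(out)

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for seg in self.segments:
            out = out + seg.velocity(t)
        return out if out.ndim else float(out)

    def displacement_vec(self, t) -> np.ndarray:
        """3-vector displacement; shape (..., 3)."""
        d = np.asarray(self.displacement(t), dtype=float)
        return np.multiply.outer(d, self.axis_direction)

    def rotated(self, angle_deg: float) -> "MotionProfile":
        """Same timing with the axis rotated about the depth (z) axis."""
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return replace(self, axis_direction=rz @ self.axis_direction)


def build_protocol(
    kind: str,
    speed: float = 5.0,
    range_mm: float = 20.0,
    n_round_trips: int = 5,
    accel: float = STAGE_ACCEL_MM_S2,
    dwell_s: float = 1.0,
    start_time: float = 0.0,
    axis_direction=(1.0, 0.0, 0.0),
) -> MotionProfile:
    """Build a stage motion protocol.

    ``kind='single_speed'``: ``n_round_trips`` out-and-back round trips over
    ``range_mm`` at one speed, with a dwell between legs.
    ``kind='mixed'``: each round trip goes out at 4 mm/s and back at 2 mm/s,
    mixing two speed levels within one trip.
    """
    if range_mm <= 0:
        raise ValueError("range_mm must be > 0")
    if kind not in ("single_speed", "mixed"):
        raise ValueError(f"unknown protocol kind {kind!r}")

    if kind == "single_speed":
        leg_speeds = [speed, speed] * n_round_trips
    else:
        leg_speeds = [4.0, 2.0] * n_round_trips
    for v in leg_speeds:
        if v > STAGE_MAX_SPEED_MM_S:
            raise ValueError(
                f"speed {v} mm/s exceeds the combined stage maximum "
                f"of {STAGE_MAX_SPEED_MM_S} mm/s"
            )

    segments = []
    t = start_time
    sign = 1.0
    for v in leg_speeds:
        seg = TrapezoidSegment(start_time=t, distance=sign * range_mm, accel=accel, vmax=v)
        segments.append(seg)
        t = seg.end_time + dwell_s
        sign = -sign
    return MotionProfile(segments=tuple(segments), axis_direction=np.asarray(axis_direction, float))
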