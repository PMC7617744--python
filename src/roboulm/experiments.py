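"""Canned study protocols: the closed-loop residual experiment and the
minimum-move search used for headline numbers."""

from __future__ import annotations

from .control import LoopTimings, run_async_loop
from .kinematics import TrapezoidSegment, build_protocol
from .residual import detect_onset, residual_stats
from .scene import default_scene

__all__ = ["closed_loop_residual", "min_move_reaching_vmax"]


def min_move_reaching_vmax(vmax: float = 50.0, accel: float = 250.0,
                           tol: float = 1e-6) -> float:
    """Bisection search for the shortest move whose trapezoidal profile
    attains ``vmax`` (peak speed measured on the simulated profile)."""
    lo, hi = tol, 1e4
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        seg = TrapezoidSegment(0.0, mid, accel, vmax)
        if seg.peak_speed >= vmax - 1e-12:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def closed_loop_residual(
    speed_mm_s: float,
    seeds,
    n_round_trips: int = 2,
    measurement: str = "image",
    latency_model: str = "proportional",
    n_speckle: int = 400,
    n_bubbles: int = 20,
) -> list[dict]:
    """Run the tracking loop per seed and return in-motion residual stats.

    Each run drives the single-speed protocol (20 mm legs, 3 mm/s^2 stage
    acceleration, 1 s dwell) with the stated processing latencies and robot
    kinematics, logs the landmark residual per acquired frame, flags the
    in-motion window (0.1 mm onset threshold) and summarises the residual
    magnitude over it.
    """
    out = []
    for seed in seeds:
        scene = default_scene(seed=int(seed), n_speckle=n_speckle,
                              n_bubbles=n_bubbles)
        profile = build_protocol("single_speed", speed_mm_s, 20.0,
                                 n_round_trips, start_time=1.0)
        log = run_async_loop(
            scene, profile,
            timings=LoopTimings(latency_model=latency_model),
            duration_s=profile.end_time + 1.0,
            seed=int(seed),
            measurement=measurement,
        )
        series = log.frames.rename(columns={"residual_mm": "displacement_mm"})[
            ["t_s", "displacement_mm"]
        ].assign(in_motion=False)
        series = detect_onset(series)
        stats = residual_stats(series)
        stats["in_fov_fraction"] = float(log.frames["in_fov"].mean())
        stats["seed"] = int(seed)
        out.append(stats)
    return out
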