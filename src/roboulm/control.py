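"""Event-driven simulation of the asynchronous acquire / process / servo loop.

Acquisition emits frames at a strictly uniform volume rate no matter how long
processing takes.  Each sequential processing cycle beamforms the latest
available frame on a small low-resolution crop, estimates the target's
translation relative to the very first frame, and commands the robot to
cancel it (clamped by a safety workspace).  Per-stage latencies are drawn
from their configured ranges each cycle; the robot executes straight-line
trapezoidal moves and, for the short corrections typical of tracking, never
reaches cruise speed (triangular profiles).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import (
    ProbeModel,
    PSFModel,
    Volume,
    VolumeGrid,
    default_psf,
    render_bmode,
    voxel_pitch_two_wavelengths,
)
from .kinematics import MotionProfile, TrapezoidSegment
from .registration import estimate_translation
from .scene import PhantomScene, scene_at_time

__all__ = [
    "LoopTimings",
    "RobotState",
    "RobotMove",
    "ProbeTrajectory",
    "SafetyWorkspace",
    "TrackingLog",
    "robot_move",
    "clamp_command",
    "crop_volume",
    "run_async_loop",
]

#: Robot kinematic limits used for probe repositioning.
ROBOT_ACCEL_MM_S2 = 250.0
ROBOT_VMAX_MM_S = 50.0


@dataclass(frozen=True)
class LoopTimings:
    """Per-stage processing latencies (seconds).

    ``latency_model`` selects how the stage durations inside the stated
    ranges arise each cycle:

    * ``"proportional"`` (default): registration time grows with the offset
      being registered (iteration count scales with the initial
      misalignment) and the robot-control stage lasts as long as the
      commanded trapezoidal move (its duration is a function of move
      distance), floored at the range minimum.  Both therefore stay inside
      their stated ranges while being driven by the loop state.
    * ``"uniform"``: both stage durations are drawn uniformly from their
      ranges, independent of state.
    """

    beamform_latency: float = 0.04
    registration_latency: tuple[float, float] = (0.04, 0.3)
    robot_command_latency: tuple[float, float] = (0.03, 0.25)
    latency_model: str = "proportional"
    registration_scale_mm: float = 6.25  # offset at which latency saturates

    def __post_init__(self):
        for lo, hi in (self.registration_latency, self.robot_command_latency):
            if lo < 0 or hi < lo:
                raise ValueError("latency ranges must satisfy 0 <= min <= max")
        if self.beamform_latency < 0:
            raise ValueError("beamform latency must be >= 0")
        if self.latency_model not in ("proportional", "uniform"):
            raise ValueError(f"unknown latency model {self.latency_model!r}")

    def draw_registration(self, offset_mm: float, rng) -> float:
        lo, hi = self.registration_latency
        if self.latency_model == "uniform":
            return float(rng.uniform(lo, hi))
        frac = min(abs(offset_mm) / self.registration_scale_mm, 1.0)
        jitter = rng.normal(0.0, 0.01)
        return float(np.clip(lo + (hi - lo) * frac + jitter, lo, hi))

    def robot_stage(self, move_duration_s: float, rng) -> float:
        lo, hi = self.robot_command_latency
        if self.latency_model == "uniform":
            return float(rng.uniform(lo, hi))
        return float(max(lo, move_duration_s))


@dataclass(frozen=True)
class RobotState:
    pose: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm offsets
    accel: float = ROBOT_ACCEL_MM_S2
    vmax: float = ROBOT_VMAX_MM_S
    busy_until: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "pose", np.asarray(self.pose, float))


@dataclass(frozen=True)
class RobotMove:
    """Straight-line trapezoidal move; pose is defined for all t >= t_start."""

    start_pose: np.ndarray
    target_pose: np.ndarray
    segment: TrapezoidSegment

    @property
    def direction(self) -> np.ndarray:
        d = self.target_pose - self.start_pose
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.zeros(3)

    @property
    def arrival_time(self) -> float:
        return self.segment.end_time

    def pose_at(self, t) -> np.ndarray:
        disp = np.asarray(self.segment.displacement(t), float)
        return self.start_pose + np.multiply.outer(disp, self.direction)


def robot_move(state: RobotState, target_pose, t_start: float) -> tuple[RobotState, RobotMove]:
    """Start a trapezoidal move; errors if the robot is still busy."""
    if t_start < state.busy_until - 1e-12:
        raise ValueError("robot busy until %.4f s" % state.busy_until)
    target_pose = np.asarray(target_pose, float)
    dist = float(np.linalg.norm(target_pose - state.pose))
    seg = TrapezoidSegment(start_time=t_start, distance=dist,
                           accel=state.accel, vmax=state.vmax)
    move = RobotMove(start_pose=state.pose, target_pose=target_pose, segment=seg)
    new_state = replace(state, pose=target_pose, busy_until=seg.end_time)
    return new_state, move


class ProbeTrajectory:
    """Piecewise pose history built from successive robot moves."""

    def __init__(self, initial_pose=(0.0, 0.0, 0.0)):
        self._moves: list[RobotMove] = []
        self._starts: list[float] = []
        self._initial = np.asarray(initial_pose, float)

    def add(self, move: RobotMove) -> None:
        if self._starts and move.segment.start_time < self._starts[-1]:
            raise ValueError("moves must be added in time order")
        self._moves.append(move)
        self._starts.append(move.segment.start_time)

    def pose_at(self, t: float) -> np.ndarray:
        i = bisect.bisect_right(self._starts, t) - 1
        if i < 0:
            return self._initial.copy()
        return self._moves[i].pose_at(t)

    def pose_series(self, times: np.ndarray) -> np.ndarray:
        return np.array([self.pose_at(float(t)) for t in np.asarray(times, float)])


@dataclass(frozen=True)
class SafetyWorkspace:
    """Closed-interval safe box for commanded probe positions (mm)."""

    lateral: tuple[float, float] = (-50.0, 50.0)
    elevational: tuple[float, float] = (-50.0, 50.0)
    depth: tuple[float, float] = (-5.0, 5.0)
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))

    def contains(self, pose) -> bool:
        p = np.asarray(pose, float) - self.center
        return bool(
            self.lateral[0] <= p[0] <= self.lateral[1]
            and self.elevational[0] <= p[1] <= self.elevational[1]
            and self.depth[0] <= p[2] <= self.depth[1]
        )


def clamp_command(workspace: SafetyWorkspace, target_pose) -> tuple[np.ndarray, bool]:
    """Withhold (rather than clip) commands that leave the safe workspace."""
    target_pose = np.asarray(target_pose, float)
    if workspace.contains(target_pose):
        return target_pose, False
    return target_pose, True


def crop_volume(volume: Volume, center_mm, size_mm) -> Volume:
    """Sub-volume of physical size ``size_mm`` centred at ``center_mm``."""
    g = volume.grid
    size = np.broadcast_to(np.asarray(size_mm, float), (3,))
    n = np.maximum(np.round(size / g.pitch).astype(int), 1)
    c_idx = g.mm_to_index(np.asarray(center_mm, float))
    lo = np.round(c_idx - (n - 1) / 2.0).astype(int)
    hi = lo + n
    if np.any(lo < 0) or np.any(hi > np.asarray(g.shape)):
        raise ValueError("crop exceeds volume extent")
    sub = volume.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub_grid = VolumeGrid(
        origin=g.index_to_mm(lo), pitch=g.pitch, shape=tuple(n),
        frame_time=g.frame_time,
    )
    return Volume(data=sub.copy(), grid=sub_grid)


@dataclass
class TrackingLog:
    """Per-cycle and per-frame records of one closed-loop run."""

    cycles: pd.DataFrame
    frames: pd.DataFrame
    volume_rate_hz: float

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)


def run_async_loop(
    scene: PhantomScene,
    profile: MotionProfile,
    timings: LoopTimings = LoopTimings(),
    workspace: SafetyWorkspace = SafetyWorkspace(),
    duration_s: float = 15.0,
    seed: int = 0,
    volume_rate_hz: float = 85.0,
    probe: ProbeModel | None = None,
    psf: PSFModel | None = None,
    crop_size_mm: float = 12.5,
    crop_pitch_mm: float | None = None,
    crop_center: np.ndarray | None = None,
    tracking_enabled: bool = True,
    servo_axial: bool = False,
    re_reference: bool = False,
    flow_speed_mm_s: float = 1.0,
    noise_sigma: float = 0.02,
    measurement: str = "image",
    truth_noise_mm: float = 0.05,
    robot_accel: float = ROBOT_ACCEL_MM_S2,
    robot_vmax: float = ROBOT_VMAX_MM_S,
) -> TrackingLog:
    """Simulate the asynchronous acquisition / registration / servo timeline.

    ``measurement='image'`` renders the cropped low-resolution volume each
    cycle and estimates the translation by registration against the first
    frame; ``'truth'`` replaces the estimate by the ground-truth in-image
    displacement plus Gaussian noise (fast path for property tests).

    The landmark residual (target displacement minus probe displacement,
    lateral + elevational) is logged for every acquired frame.
    """
    rng = np.random.default_rng(seed)
    probe = probe if probe is not None else ProbeModel()
    psf = psf if psf is not None else default_psf(probe)
    if crop_pitch_mm is None:
        crop_pitch_mm = round(voxel_pitch_two_wavelengths(probe), 1)
    if crop_center is None:
        crop_center = probe.world_to_probe(scene.landmark_center)[0]
    grid = VolumeGrid.centered(crop_center, crop_size_mm, crop_pitch_mm)

    traj = ProbeTrajectory()
    robot = RobotState(accel=robot_accel, vmax=robot_vmax)
    dt = 1.0 / volume_rate_hz

    def render_at(t_frame: float) -> Volume:
        sc = scene_at_time(scene, profile, t_frame, flow_speed=flow_speed_mm_s)
        pr = replace(probe, position=traj.pose_at(t_frame))
        g = replace(grid, frame_time=t_frame)
        return render_bmode(sc, pr, g, psf, noise_sigma=noise_sigma, rng=rng)

    reference = render_at(0.0) if measurement == "image" else None
    prev_estimate: np.ndarray | None = None  # last absolute target estimate

    cycles = []
    t = dt  # first processed frame becomes available one interval in
    while t < duration_s:
        # sequential loop: the previous round's robot stage must complete
        t = max(t, robot.busy_until)
        frame_k = int(np.floor(t / dt + 1e-9))
        t_frame = frame_k * dt

        pose_at_frame = traj.pose_at(t_frame)
        true_resid = profile.displacement_vec(t_frame) - pose_at_frame
        skipped = False
        if measurement == "image":
            current = render_at(t_frame)
            init = None if prev_estimate is None else prev_estimate - pose_at_frame
            result = estimate_translation(reference, current, init=init,
                                          n_pyramid_levels=2,
                                          max_iter_per_level=30,
                                          max_points=6000)
            det = result.transform.translation
            if (not result.converged) or np.any(np.abs(det) > crop_size_mm):
                skipped = True
                det = np.zeros(3)
        else:
            det = true_resid + rng.normal(0.0, truth_noise_mm, size=3)

        reg_lat = timings.draw_registration(np.linalg.norm(det[:2]), rng)
        t_done = t + timings.beamform_latency + reg_lat

        issued = False
        withheld = False
        stage_lat = 0.0
        if tracking_enabled and not skipped:
            target = pose_at_frame + det
            if not servo_axial:
                target = target.copy()
                target[2] = robot.pose[2]
            target, withheld = clamp_command(workspace, target)
            if not withheld:
                # the move starts when the command is dispatched; the
                # robot-control stage lasts at least as long as the move
                robot, move = robot_move(robot, target, t_done)
                stage_lat = timings.robot_stage(move.segment.duration, rng)
                robot = replace(
                    robot,
                    busy_until=max(move.arrival_time, t_done + stage_lat),
                )
                traj.add(move)
                issued = True
                prev_estimate = pose_at_frame + det
                if re_reference and measurement == "image":
                    reference = render_at(move.arrival_time)
        if not issued and not skipped:
            prev_estimate = pose_at_frame + det

        cycles.append(dict(
            t_cycle_start=t, t_frame=t_frame,
            det_dx_mm=det[0], det_dy_mm=det[1], det_dz_mm=det[2],
            reg_latency_s=reg_lat, cmd_latency_s=stage_lat,
            cmd_issued=issued, withheld=withheld, skipped=skipped,
        ))
        # a new round never reprocesses the same frame: advance at least to
        # the next acquisition even if all latencies are zero
        t = max(t_done, (frame_k + 1) * dt)

    n_frames = int(np.floor(duration_s * volume_rate_hz))
    times = np.arange(n_frames) * dt
    disp = profile.displacement_vec(times)
    pose = traj.pose_series(times)
    resid = disp - pose
    resid_mm = np.linalg.norm(resid[:, :2], axis=1)  # lateral + elevational
    in_fov = (np.abs(resid[:, 0]) <= probe.fov_halfwidth_mm) & (
        np.abs(resid[:, 1]) <= probe.fov_halfwidth_mm
    )
    frames = pd.DataFrame(dict(
        t_s=times,
        target_dx_mm=disp[:, 0], target_dy_mm=disp[:, 1], target_dz_mm=disp[:, 2],
        robot_x_mm=pose[:, 0], robot_y_mm=pose[:, 1], robot_z_mm=pose[:, 2],
        resid_dx_mm=resid[:, 0], resid_dy_mm=resid[:, 1], resid_dz_mm=resid[:, 2],
        residual_mm=resid_mm, in_fov=in_fov,
    ))
    return TrackingLog(
        cycles=pd.DataFrame(cycles), frames=frames, volume_rate_hz=volume_rate_hz
    )
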