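"""End-to-end commands tying simulation, tracking, reconstruction and
evaluation together.  Each command is a plain function over a
:class:`~roboulm.config.RunConfig`; the CLI wraps them thinly.

Every table / summary written by a command carries the config hash, and
commands that consume another command's artefacts refuse mismatched hashes.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import fsc as fsc_mod
from . import residual as residual_mod
from . import ulm as ulm_mod
from .config import ConfigError, RunConfig
from .control import LoopTimings, SafetyWorkspace, TrackingLog, run_async_loop
from .imaging import (
    ProbeModel,
    Volume,
    VolumeGrid,
    default_psf,
    render_bmode,
    render_contrast,
    voxel_pitch_two_wavelengths,
)
from .io import save_volume
from .kinematics import MotionProfile, build_protocol
from .registration import (
    RigidTransform,
    estimate_rigid_lm,
    lagrangian_accumulate,
    transforms_to_frame,
)
from .scene import PhantomScene, default_scene, scene_at_time

__all__ = [
    "build_scene",
    "build_profile",
    "build_probe",
    "cmd_simulate",
    "cmd_track",
    "cmd_evaluate",
    "cmd_reconstruct",
    "cmd_fsc",
]

_DIRECTIONS = {
    "lateral": (1.0, 0.0, 0.0),
    "elevational": (0.0, 1.0, 0.0),
    # default "arbitrary" direction: 45 degrees between lateral and elevational
    "arbitrary": (np.sqrt(0.5), np.sqrt(0.5), 0.0),
}


def build_scene(config: RunConfig) -> PhantomScene:
    s = config.scene
    return default_scene(
        seed=s.seed + config.seed,
        n_speckle=s.n_speckle,
        n_bubbles=s.n_bubbles,
        channel_radius=s.channel_radius_mm,
        crossing_angle_deg=s.crossing_angle_deg,
        channel_depth=s.channel_depth_mm,
    )


def build_profile(config: RunConfig) -> MotionProfile:
    p = config.protocol
    if p.direction not in _DIRECTIONS:
        raise ConfigError(f"unknown protocol direction {p.direction!r}")
    return build_protocol(
        kind=p.kind,
        speed=p.speed_mm_s,
        range_mm=p.range_mm,
        n_round_trips=p.n_round_trips,
        accel=p.accel_mm_s2,
        dwell_s=p.dwell_s,
        start_time=p.start_time_s,
        axis_direction=_DIRECTIONS[p.direction],
    )


def build_probe(config: RunConfig) -> ProbeModel:
    pr = config.probe
    return ProbeModel(
        aperture_mm=tuple(pr.aperture_mm),
        center_frequency_mhz=pr.center_frequency_mhz,
        sound_speed_m_s=pr.sound_speed_m_s,
        fov_halfwidth_mm=pr.fov_halfwidth_mm,
    )


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.hash
    return df


def _check_hash(df: pd.DataFrame, config: RunConfig, what: str) -> None:
    if "config_hash" in df.columns:
        hashes = set(df["config_hash"].unique())
        if hashes != {config.hash}:
            raise ConfigError(
                f"{what} was produced by config {hashes} but current config "
                f"hash is {config.hash}; refusing to mix artefacts"
            )


def cmd_simulate(config: RunConfig, out_dir) -> dict:
    """Render a static-probe acquisition: frame volumes plus ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = build_scene(config)
    profile = build_profile(config)
    probe = build_probe(config)
    psf = default_psf(probe)
    rng = np.random.default_rng(config.seed)

    rate = config.loop.volume_rate_hz
    duration = config.loop.duration_s
    pitch = round(voxel_pitch_two_wavelengths(probe), 1)
    crop_center = probe.world_to_probe(scene.landmark_center)[0]
    grid = VolumeGrid.centered(crop_center, config.loop.crop_size_mm, pitch)

    n_frames = int(np.floor(duration * rate))
    rows, truth_rows = [], []
    for k in range(n_frames):
        t = k / rate
        sc = scene_at_time(scene, profile, t, config.scene.flow_speed_mm_s)
        g = replace(grid, frame_time=t)
        bmode = render_bmode(sc, probe, g, psf,
                             noise_sigma=config.loop.noise_sigma, rng=rng)
        contrast = render_contrast(sc, probe, g, psf,
                                   noise_sigma=config.loop.noise_sigma, rng=rng)
        save_volume(bmode, out / f"bmode_{k:04d}.nii")
        save_volume(contrast, out / f"contrast_{k:04d}.nii")
        rows.append(dict(frame=k, t_s=t, probe_x_mm=0.0, probe_y_mm=0.0,
                         probe_z_mm=0.0))
        lm = sc.landmark_center
        truth_rows.append(dict(frame=k, t_s=t, landmark_x_mm=lm[0],
                               landmark_y_mm=lm[1], landmark_z_mm=lm[2]))
        for b, p in enumerate(sc.bubble_positions()):
            truth_rows[-1][f"bubble{b}_x_mm"] = p[0]
            truth_rows[-1][f"bubble{b}_y_mm"] = p[1]
            truth_rows[-1][f"bubble{b}_z_mm"] = p[2]

    _stamp(pd.DataFrame(rows), config).to_csv(out / "probe_pose.csv", index=False)
    _stamp(pd.DataFrame(truth_rows), config).to_csv(out / "ground_truth.csv",
                                                    index=False)
    _stamp(scene.to_table(), config).to_csv(out / "scene_scatterers.csv",
                                            index=False)
    config.to_yaml(out / "config.yaml")
    manifest = dict(config_hash=config.hash, n_frames=n_frames,
                    volume_rate_hz=rate)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_loop(config: RunConfig, scene, profile, probe) -> TrackingLog:
    lp = config.loop
    timings = LoopTimings(
        beamform_latency=lp.beamform_latency_s,
        registration_latency=tuple(lp.registration_latency_s),
        robot_command_latency=tuple(lp.robot_command_latency_s),
        latency_model=lp.latency_model,
    )
    return run_async_loop(
        scene=scene,
        profile=profile,
        timings=timings,
        workspace=SafetyWorkspace(),
        duration_s=lp.duration_s,
        seed=config.seed,
        volume_rate_hz=lp.volume_rate_hz,
        probe=probe,
        crop_size_mm=lp.crop_size_mm,
        tracking_enabled=lp.tracking_enabled,
        flow_speed_mm_s=config.scene.flow_speed_mm_s,
        noise_sigma=lp.noise_sigma,
        measurement=lp.measurement,
    )


def cmd_track(config: RunConfig, out_dir) -> dict:
    """Run the asynchronous tracking loop; write logs and a residual summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = build_scene(config)
    profile = build_profile(config)
    probe = build_probe(config)
    log = _run_loop(config, scene, profile, probe)

    _stamp(log.frames, config).to_csv(out / "tracking_frames.csv", index=False)
    _stamp(log.cycles, config).to_csv(out / "tracking_cycles.csv", index=False)

    series = log.frames.rename(columns={"residual_mm": "displacement_mm"})[
        ["t_s", "displacement_mm"]
    ].assign(dx_mm=log.frames["resid_dx_mm"], dy_mm=log.frames["resid_dy_mm"],
             dz_mm=log.frames["resid_dz_mm"], in_motion=False)
    series = residual_mod.detect_onset(series)
    summary = dict(config_hash=config.hash,
                   in_fov_fraction=float(log.frames["in_fov"].mean()))
    if series["in_motion"].any():
        stats = residual_mod.residual_stats(series)
        summary.update(mean_residual_mm=stats["mean_mm"],
                       std_residual_mm=stats["std_mm"],
                       n_in_motion_frames=stats["n_frames"],
                       fraction_within_2mm=stats["fraction_within"](2.0))
    config.to_yaml(out / "config.yaml")
    (out / "residual_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def cmd_evaluate(
    config: RunConfig,
    out_dir,
    track_frames: pd.DataFrame | None = None,
    eval_rate_hz: float = 10.0,
    roi_halfwidth_mm: float = 1.2,
) -> dict:
    """Image-based residual evaluation: 0.1 mm render + weighted centroiding.

    Re-renders the landmark neighbourhood at the evaluation pitch for a
    subsampled set of frames of a tracking run, localises the landmark by
    weighted centroiding (ROI follows the previous centroid), and summarises
    the in-motion displacement.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = build_scene(config)
    profile = build_profile(config)
    probe = build_probe(config)
    psf = default_psf(probe)
    rng = np.random.default_rng(config.seed + 1)

    if track_frames is None:
        p = out / "tracking_frames.csv"
        if not p.exists():
            raise FileNotFoundError(f"no tracking_frames.csv under {out}")
        track_frames = pd.read_csv(p)
    _check_hash(track_frames, config, "tracking log")

    times = track_frames["t_s"].to_numpy()
    poses = track_frames[["robot_x_mm", "robot_y_mm", "robot_z_mm"]].to_numpy()
    t_eval = np.arange(times[0], times[-1], 1.0 / eval_rate_hz)
    pose_eval = np.column_stack([np.interp(t_eval, times, poses[:, i])
                                 for i in range(3)])

    lm0 = probe.world_to_probe(scene.landmark_center)[0]
    grid = VolumeGrid.centered(lm0, 6.0, config.recon.pitch_mm)
    centroids, roi_center = [], lm0
    for t, pose in zip(t_eval, pose_eval):
        sc = scene_at_time(scene, profile, float(t), config.scene.flow_speed_mm_s)
        pr = replace(probe, position=pose)
        vol = render_bmode(sc, pr, replace(grid, frame_time=float(t)), psf,
                           noise_sigma=config.loop.noise_sigma, rng=rng)
        roi = np.column_stack([roi_center - roi_halfwidth_mm,
                               roi_center + roi_halfwidth_mm])
        c = residual_mod.weighted_centroid(vol, roi)
        centroids.append(c)
        roi_center = c
    centroids = np.asarray(centroids)

    series = residual_mod.displacement_series(t_eval, centroids)
    series = residual_mod.detect_onset(series)
    _stamp(series, config).to_csv(out / "displacement_series.csv", index=False)
    summary = dict(config_hash=config.hash, eval_pitch_mm=config.recon.pitch_mm)
    if series["in_motion"].any():
        stats = residual_mod.residual_stats(series)
        summary.update(mean_residual_mm=stats["mean_mm"],
                       std_residual_mm=stats["std_mm"],
                       n_in_motion_frames=stats["n_frames"])
    (out / "evaluation_summary.json").write_text(json.dumps(summary, indent=2))

    try:  # summary figure; headless backends may vary
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(series["t_s"], series["displacement_mm"], lw=1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("landmark displacement (mm)")
        fig.tight_layout()
        fig.savefig(out / "displacement_series.png", dpi=120)
        plt.close(fig)
    except Exception:
        pass
    return summary


def _extract_bubble_patches(volumes, n_patches=5, radius_vox=4, min_sep_vox=6):
    """Pick bright, isolated peaks across frames as single-bubble patches."""
    candidates = []
    for vol in volumes:
        d = vol.data
        from scipy import ndimage as ndi

        mx = ndi.maximum_filter(d, size=3, mode="constant")
        peaks = np.argwhere((d == mx) & (d > 0))
        for p in peaks:
            if np.all(p >= radius_vox) and np.all(
                p < np.asarray(d.shape) - radius_vox
            ):
                candidates.append((float(d[tuple(p)]), vol, p))
    candidates.sort(key=lambda c: -c[0])
    patches, used = [], []
    for amp, vol, p in candidates:
        if any(np.all(np.abs(p - q) < min_sep_vox) for q in used):
            continue
        sl = tuple(slice(p[i] - radius_vox, p[i] + radius_vox + 1) for i in range(3))
        sub = vol.data[sl]
        g = VolumeGrid(origin=vol.grid.index_to_mm(p - radius_vox),
                       pitch=vol.grid.pitch, shape=sub.shape)
        patches.append(Volume(data=sub.copy(), grid=g))
        used.append(p)
        if len(patches) >= n_patches:
            break
    return patches


def cmd_reconstruct(config: RunConfig, out_dir, use_registration: bool = True) -> dict:
    """Offline chain: residual-motion registration, motion-corrected ULM
    localisation/tracking, super-resolved maps and odd/even FSC.

    With- and without-correction density maps are both written for
    comparison.  ``use_registration=False`` substitutes ground-truth motion
    for the 6-DoF registration (fast path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = build_scene(config)
    profile = build_profile(config)
    probe = build_probe(config)
    psf = default_psf(probe)
    rng = np.random.default_rng(config.seed + 2)

    # probe trajectory from the closed loop
    log = _run_loop(config, scene, profile, probe)
    times = log.frames["t_s"].to_numpy()
    poses = log.frames[["robot_x_mm", "robot_y_mm", "robot_z_mm"]].to_numpy()

    rc = config.recon
    t_rec = np.arange(0.0, min(rc.duration_s, times[-1]), 1.0 / rc.frame_rate_hz)
    pose_rec = np.column_stack([np.interp(t_rec, times, poses[:, i])
                                for i in range(3)])

    lm0 = probe.world_to_probe(scene.landmark_center)[0]
    reg_grid = VolumeGrid.centered(lm0, 4.0, rc.pitch_mm)
    cross0 = np.array([0.0, -1.0, config.scene.channel_depth_mm])
    ceus_grid = VolumeGrid.centered(cross0, (8.0, 6.0, 2.0), rc.pitch_mm)

    bmode_frames, ceus_frames = [], []
    for t, pose in zip(t_rec, pose_rec):
        sc = scene_at_time(scene, profile, float(t), config.scene.flow_speed_mm_s)
        pr = replace(probe, position=pose)
        bmode_frames.append(render_bmode(
            sc, pr, replace(reg_grid, frame_time=float(t)), psf,
            noise_sigma=config.loop.noise_sigma, rng=rng))
        ceus_frames.append(render_contrast(
            sc, pr, replace(ceus_grid, frame_time=float(t)), psf,
            noise_sigma=config.loop.noise_sigma, rng=rng))

    # --- residual motion: 6-DoF rigid registration with warm start ---
    transforms, converged = [], []
    if use_registration:
        prev = None
        for vol in bmode_frames:
            res = estimate_rigid_lm(bmode_frames[0], vol, init=prev)
            transforms.append(res.transform)
            converged.append(res.converged)
            prev = res.transform
    else:
        for t, pose in zip(t_rec, pose_rec):
            resid = profile.displacement_vec(float(t)) - pose
            resid0 = profile.displacement_vec(float(t_rec[0])) - pose_rec[0]
            transforms.append(RigidTransform(translation=resid - resid0))
            converged.append(True)
    _stamp(transforms_to_frame(transforms, converged), config).to_csv(
        out / "transforms.csv", index=False)

    # Lagrangian-corrected mean contrast volume (and uncorrected comparison)
    ceus_corr, _ = lagrangian_accumulate(ceus_frames, transforms, reducer="mean")
    identity = [RigidTransform() for _ in ceus_frames]
    ceus_uncorr, _ = lagrangian_accumulate(ceus_frames, identity, reducer="mean")
    save_volume(ceus_corr, out / "ceus_mean_corrected.nii")
    save_volume(ceus_uncorr, out / "ceus_mean_uncorrected.nii")

    # --- ULM chain ---
    noise_std = float(np.std([v.data for v in ceus_frames[:3]]))
    floor = rc.noise_floor_rel * noise_std
    suppressed = [ulm_mod.suppress_background(v, noise_floor=floor)
                  for v in ceus_frames]
    patches = _extract_bubble_patches(suppressed[:10])
    if len(patches) >= 2:
        template = ulm_mod.estimate_psf(patches)
    else:  # too few isolated bubbles: fall back to the imaging PSF model
        tpl_grid = VolumeGrid.centered((0, 0, 0), 0.9, rc.pitch_mm)
        sigma = psf.sigma_mm
        ax = [a for a in tpl_grid.axes()]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        tpl = np.exp(-0.5 * ((gx / sigma[0]) ** 2 + (gy / sigma[1]) ** 2
                             + (gz / sigma[2]) ** 2))
        template = ulm_mod.PSFTemplate(data=tpl / tpl.max(),
                                       pitch_mm=tpl_grid.pitch)

    def localisations(correct: bool):
        per_frame = []
        for k, vol in enumerate(suppressed):
            scores = ulm_mod.ncc_map(vol, template)
            locs = ulm_mod.localise(scores, vol, threshold=rc.ncc_threshold,
                                    upsample=rc.upsample, frame=k)
            if correct:
                inv = transforms[k].inverse()
                locs = [ulm_mod.Localisation(inv.apply(l.position_mm),
                                             l.frame, l.ncc_score, l.intensity)
                        for l in locs]
            per_frame.append(locs)
        return per_frame

    maps = {}
    map_grid = VolumeGrid.centered(cross0, (5.0, 4.0, 1.0), rc.map_pitch_mm)
    all_tracks = {}
    for label, correct in (("corrected", True), ("uncorrected", False)):
        per_frame = localisations(correct)
        tracks = ulm_mod.link_tracks(per_frame, rc.frame_rate_hz,
                                     max_speed_mm_s=rc.max_link_speed_mm_s)
        tracks = ulm_mod.persistence_filter(tracks, rc.persistence_frames)
        all_tracks[label] = tracks
        m = ulm_mod.accumulate_maps(tracks, map_grid, rc.frame_rate_hz)
        maps[label] = m
        sm = ulm_mod.smooth_maps(m)
        save_volume(m.density, out / f"density_{label}.nii")
        save_volume(m.speed, out / f"speed_{label}.nii")
        save_volume(sm.density, out / f"density_{label}_smoothed.nii")
        save_volume(sm.speed, out / f"speed_{label}_smoothed.nii")
        _stamp(ulm_mod.tracks_to_frame(tracks), config).to_csv(
            out / f"tracks_{label}.csv", index=False)

    summary = dict(config_hash=config.hash,
                   n_frames=len(ceus_frames),
                   n_tracks_corrected=len(all_tracks["corrected"]),
                   n_tracks_uncorrected=len(all_tracks["uncorrected"]))

    # odd/even FSC on a cubic crop of the corrected density map
    tracks = all_tracks["corrected"]
    if len(tracks) >= 2:
        n_cube = int(min(map_grid.shape))
        cube = VolumeGrid.centered(map_grid.center, n_cube * rc.map_pitch_mm,
                                   rc.map_pitch_mm)
        ma, mb = fsc_mod.split_odd_even(tracks, cube, rc.frame_rate_hz)
        curve = fsc_mod.fsc_curve(ma.density, mb.density)
        resv = fsc_mod.fsc_resolution(curve)
        _stamp(curve.to_frame(), config).to_csv(out / "fsc_curve.csv", index=False)
        summary.update(fsc_resolution_um=resv.resolution_um,
                       fsc_crossed=resv.crossed)
    else:
        summary.update(warning="no localisations survived; maps are empty")
    config.to_yaml(out / "config.yaml")
    (out / "reconstruction_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def cmd_fsc(config: RunConfig, out_dir, tracks_csv=None) -> dict:
    """FSC between odd/even-trajectory density maps of an existing track set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = Path(tracks_csv) if tracks_csv else out / "tracks_corrected.csv"
    df = pd.read_csv(path)
    _check_hash(df, config, "tracks table")
    tracks = []
    for _, grp in df.groupby("track_id"):
        tr = ulm_mod.Track(frames=list(grp["frame"]),
                           positions_mm=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                           scores=[1.0] * len(grp))
        tracks.append(tr.finalise(config.recon.frame_rate_hz))
    rc = config.recon
    pos = np.vstack([t.positions_mm for t in tracks])
    center = np.median(pos, axis=0)
    extent = float(np.max(np.ptp(pos, axis=0)) + 0.2)
    # cap the cube so sparse, wide track sets stay tractable in memory
    n = min(int(np.ceil(extent / rc.map_pitch_mm)), 256)
    cube = VolumeGrid.centered(center, n * rc.map_pitch_mm, rc.map_pitch_mm)
    ma, mb = fsc_mod.split_odd_even(tracks, cube, rc.frame_rate_hz)
    curve = fsc_mod.fsc_curve(ma.density, mb.density)
    resv = fsc_mod.fsc_resolution(curve)
    _stamp(curve.to_frame(), config).to_csv(out / "fsc_curve.csv", index=False)
    summary = dict(config_hash=config.hash, fsc_resolution_um=resv.resolution_um,
                   fsc_crossed=resv.crossed)
    (out / "fsc_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
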