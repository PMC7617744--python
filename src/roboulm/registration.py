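"""Rigid volume registration and Lagrangian motion-corrected accumulation.

Two estimators minimise the sum-of-squared-differences (SSD) intensity cost:

* :func:`estimate_translation` — 3-DoF translation with a regular-step
  gradient descent over a coarse-to-fine Gaussian pyramid; the fast path used
  inside the online tracking loop.
* :func:`estimate_rigid_lm` — 6-DoF rigid (3 translations mm + 3 extrinsic
  XYZ rotations deg) solved by Levenberg–Marquardt with an analytic Jacobian;
  the offline residual-motion correction path, typically warm-started from
  the previous frame's result.

Transform convention: :class:`RigidTransform` maps reference-frame physical
coordinates to moving-frame coordinates (pull-back), so the estimated
translation equals the physical displacement of the scene between the
reference and the moving frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .imaging import Volume, VolumeGrid

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "estimate_translation",
    "estimate_rigid_lm",
    "resample",
    "lagrangian_accumulate",
    "transforms_to_frame",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``y = R (x - c) + c + t`` with extrinsic XYZ Euler angles."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))      # mm

    def __post_init__(self):
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        object.__setattr__(self, "rotation_deg", np.asarray(self.rotation_deg, float))
        object.__setattr__(self, "center", np.asarray(self.center, float))

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center=np.asarray(center, float))

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        r_inv = self.matrix.T
        ang = Rotation.from_matrix(r_inv).as_euler("xyz", degrees=True)
        return RigidTransform(
            translation=-r_inv @ self.translation,
            rotation_deg=ang,
            center=self.center,
        )


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    final_cost: float
    n_iterations: int
    converged: bool


def _sample(data: np.ndarray, idx: np.ndarray):
    """Trilinear sample at fractional indices (3, N) with a validity mask."""
    shape = np.asarray(data.shape)
    valid = np.all((idx >= 0) & (idx <= (shape - 1)[:, None]), axis=0)
    vals = ndimage.map_coordinates(data, idx, order=1, mode="constant", cval=0.0)
    return vals, valid


def _pyramid(data: np.ndarray, pitch: np.ndarray, n_levels: int):
    """Fine-to-coarse Gaussian pyramid [(data, pitch), ...], 2x per level.

    Heavy pre-decimation smoothing (sigma = 2 voxels) widens each level's
    SSD basin so the coarse level can capture shifts of many fine voxels on
    pure speckle."""
    levels = [(data, pitch)]
    for _ in range(n_levels - 1):
        d, p = levels[-1]
        if min(d.shape) < 8:
            break
        sm = ndimage.gaussian_filter(d, sigma=2.0)
        levels.append((sm[::2, ::2, ::2], p * 2.0))
    return levels


def estimate_translation(
    reference: Volume,
    moving: Volume,
    n_pyramid_levels: int = 3,
    init: np.ndarray | None = None,
    max_iter_per_level: int = 60,
    min_step_mm: float = 1e-3,
    max_points: int | None = None,
) -> RegistrationResult:
    """Translation-only SSD registration (regular-step gradient descent).

    Returns the translation (mm, probe axes) that maps reference coordinates
    onto the moving frame; rotations are zero.  Coarse-to-fine over
    ``n_pyramid_levels`` with 2x downsampling per level.  ``max_points``
    subsamples the voxels entering the cost at each level (a speed knob for
    the real-time loop; ``None`` uses every voxel).
    """
    if reference.grid.shape != moving.grid.shape:
        raise ValueError("reference and moving must share grid geometry")
    ref, mov = reference.data, moving.data
    pitch = reference.grid.pitch
    if ref.std() == 0 or mov.std() == 0:
        return RegistrationResult(RigidTransform.identity(), float("inf"), 0, False)

    levels = _pyramid(ref, pitch, n_pyramid_levels)
    levels_m = _pyramid(mov, pitch, n_pyramid_levels)
    t = np.zeros(3) if init is None else np.asarray(init, float).copy()
    total_iters = 0
    final_cost = np.inf

    for (ref_l, pitch_l), (mov_l, _) in zip(reversed(levels), reversed(levels_m)):
        grad = np.stack(np.gradient(mov_l, *pitch_l))
        base_idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in ref_l.shape], indexing="ij")
        ).reshape(3, -1).astype(float)
        ref_flat = ref_l.ravel()
        if max_points is not None and base_idx.shape[1] > max_points:
            stride = int(np.ceil(base_idx.shape[1] / max_points))
            base_idx = base_idx[:, ::stride]
            ref_flat = ref_flat[::stride]

        def cost_grad(tv):
            idx = base_idx + (tv / pitch_l)[:, None]
            vals, valid = _sample(mov_l, idx)
            diff = np.where(valid, vals - ref_flat, 0.0)
            c = float(diff @ diff)
            g = np.empty(3)
            for ax in range(3):
                gax = ndimage.map_coordinates(grad[ax], idx, order=1, mode="constant")
                g[ax] = 2.0 * float(diff @ np.where(valid, gax, 0.0))
            return c, g

        step = 2.0 * float(np.max(pitch_l))
        c, g = cost_grad(t)
        it = 0
        while step > min_step_mm and it < max_iter_per_level:
            it += 1
            gn = np.linalg.norm(g)
            if gn == 0:
                break
            t_new = t - step * g / gn
            c_new, g_new = cost_grad(t_new)
            if c_new < c:
                # relax the step when the gradient direction reverses
                if np.dot(g_new, g) < 0:
                    step *= 0.5
                t, c, g = t_new, c_new, g_new
            else:
                step *= 0.5
        total_iters += it
        final_cost = c

    return RegistrationResult(
        transform=RigidTransform(translation=t),
        final_cost=final_cost,
        n_iterations=total_iters,
        converged=True,
    )


def _rotation_derivatives(rotation_deg: np.ndarray) -> np.ndarray:
    """d(R)/d(angle_deg) for the three extrinsic XYZ angles, shape (3, 3, 3)."""
    h = 1e-6
    out = np.empty((3, 3, 3))
    for k in range(3):
        dp = rotation_deg.copy(); dp[k] += h
        dm = rotation_deg.copy(); dm[k] -= h
        rp = Rotation.from_euler("xyz", dp, degrees=True).as_matrix()
        rm = Rotation.from_euler("xyz", dm, degrees=True).as_matrix()
        out[k] = (rp - rm) / (2 * h)
    return out


def estimate_rigid_lm(
    reference: Volume,
    moving: Volume,
    init: RigidTransform | None = None,
    smooth_sigma_voxels: float = 0.5,
    max_iterations: int = 200,
    step_tol: float = 1e-4,
    cost_tol: float = 1e-8,
) -> RegistrationResult:
    """6-DoF rigid SSD registration by Levenberg–Marquardt.

    Volumes are pre-smoothed (Gaussian, ``smooth_sigma_voxels``) to stabilise
    speckle gradients.  The rotation centre defaults to the volume centre.
    Damping adaptation follows the standard LM schedule (MINPACK); the
    ``converged`` flag reflects the step-size / cost-decrease tolerances.
    """
    if reference.grid.shape != moving.grid.shape:
        raise ValueError("reference and moving must share grid geometry")
    grid = reference.grid
    pitch, origin = grid.pitch, grid.origin
    center = grid.center if init is None else init.center
    p0 = (
        np.zeros(6)
        if init is None
        else np.concatenate([init.translation, init.rotation_deg])
    )

    ref = ndimage.gaussian_filter(reference.data, smooth_sigma_voxels)
    mov = ndimage.gaussian_filter(moving.data, smooth_sigma_voxels)
    if ref.std() == 0 or mov.std() == 0:
        tr = RigidTransform(p0[:3], p0[3:], center)
        return RegistrationResult(tr, float("inf"), 0, False)
    grad = np.stack(np.gradient(mov, *pitch))

    base_idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in ref.shape], indexing="ij")
    ).reshape(3, -1).astype(float)
    x_mm = base_idx * pitch[:, None] + origin[:, None]   # (3, N)
    x_c = x_mm - center[:, None]
    ref_flat = ref.ravel()

    def transform_points(p):
        rot = Rotation.from_euler("xyz", p[3:], degrees=True).as_matrix()
        return rot @ x_c + (center + p[:3])[:, None]

    def residuals(p):
        y = transform_points(p)
        idx = (y - origin[:, None]) / pitch[:, None]
        vals, valid = _sample(mov, idx)
        return np.where(valid, vals - ref_flat, 0.0)

    def jacobian(p):
        y = transform_points(p)
        idx = (y - origin[:, None]) / pitch[:, None]
        _, valid = _sample(mov, idx)
        g = np.stack([
            ndimage.map_coordinates(grad[ax], idx, order=1, mode="constant")
            for ax in range(3)
        ])                                               # (3, N)
        g = np.where(valid[None, :], g, 0.0)
        jac = np.empty((x_c.shape[1], 6))
        jac[:, :3] = g.T
        dR = _rotation_derivatives(p[3:])
        for k in range(3):
            dy = dR[k] @ x_c                             # (3, N)
            jac[:, 3 + k] = np.sum(g * dy, axis=0)
        return jac

    r0 = residuals(p0)
    cost0 = float(r0 @ r0)
    res = least_squares(
        residuals,
        p0,
        jac=jacobian,
        method="lm",
        xtol=step_tol * 1e-2,
        ftol=cost_tol,
        gtol=1e-12,
        max_nfev=max_iterations,
    )
    final_cost = float(2.0 * res.cost)
    tr = RigidTransform(res.x[:3], res.x[3:], center)
    converged = bool(res.status > 0) and final_cost <= cost0 + 1e-12
    if final_cost > cost0:  # LM must never end worse than its start
        tr = RigidTransform(p0[:3], p0[3:], center)
        final_cost = cost0
        converged = False
    return RegistrationResult(tr, final_cost, int(res.nfev), converged)


def resample(
    volume: Volume,
    transform: RigidTransform,
    fill_value: float = 0.0,
    order: int = 3,
) -> tuple[Volume, np.ndarray]:
    """Pull the moving volume back onto its grid through ``transform``.

    Samples ``volume`` at ``transform(x)`` for every grid position ``x``
    with a spline of the given ``order`` (cubic by default; ``order=1`` for
    trilinear).  Returns the resampled volume and a validity mask flagging
    voxels whose source position fell inside the support.
    """
    grid = volume.grid
    base_idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij")
    ).reshape(3, -1).astype(float)
    x_mm = base_idx * grid.pitch[:, None] + grid.origin[:, None]
    y = transform.apply(x_mm.T).T
    idx = (y - grid.origin[:, None]) / grid.pitch[:, None]
    shape = np.asarray(volume.data.shape)
    valid = np.all((idx >= 0) & (idx <= (shape - 1)[:, None]), axis=0)
    vals = ndimage.map_coordinates(volume.data, idx, order=order,
                                   mode="constant", cval=0.0)
    vals = np.where(valid, vals, fill_value)
    return (
        volume.with_data(vals.reshape(grid.shape)),
        valid.reshape(grid.shape),
    )


def _trilinear_scatter(acc, wacc, idx_f, values):
    """Scatter ``values`` at fractional indices (N, 3) with trilinear weights."""
    shape = np.asarray(acc.shape)
    i0 = np.floor(idx_f).astype(int)
    frac = idx_f - i0
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = i0 + off
        w = np.prod(np.where(off == 1, frac, 1.0 - frac), axis=1)
        ok = np.all((idx >= 0) & (idx < shape), axis=1) & (w > 0)
        if not np.any(ok):
            continue
        lin = np.ravel_multi_index(tuple(idx[ok].T), acc.shape)
        np.add.at(acc.ravel(), lin, w[ok] * values[ok])
        np.add.at(wacc.ravel(), lin, w[ok])


def lagrangian_accumulate(
    frames,
    transforms,
    reducer: str = "mean",
    grid: VolumeGrid | None = None,
) -> tuple[Volume, np.ndarray]:
    """Accumulate frames into reference coordinates (Lagrangian correction).

    ``transforms[k]`` is the registration result of (reference, frame k) —
    i.e. it maps reference coordinates to frame-k coordinates — so each frame
    voxel at position ``q`` contributes at reference position
    ``transforms[k].inverse()(q)``.  Values are scattered with trilinear
    weights and reduced (``sum`` / ``mean`` / ``max``).  Returns the reduced
    volume and the per-voxel contribution weights.
    """
    frames = list(frames)
    transforms = list(transforms)
    if len(frames) != len(transforms):
        raise ValueError("one transform per frame required")
    if not frames:
        raise ValueError("no frames")
    if reducer not in ("sum", "mean", "max"):
        raise ValueError(f"unknown reducer {reducer!r}")
    out_grid = grid if grid is not None else frames[0].grid

    acc = np.zeros(out_grid.shape)
    wacc = np.zeros(out_grid.shape)
    for frame, tr in zip(frames, transforms):
        g = frame.grid
        base_idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in g.shape], indexing="ij")
        ).reshape(3, -1).astype(float)
        q = (base_idx * g.pitch[:, None] + g.origin[:, None]).T
        y = tr.inverse().apply(q)
        idx_f = (y - out_grid.origin) / out_grid.pitch
        vals = frame.data.ravel()
        if reducer == "max":
            i0 = np.round(idx_f).astype(int)
            ok = np.all((i0 >= 0) & (i0 < np.asarray(out_grid.shape)), axis=1)
            lin = np.ravel_multi_index(tuple(i0[ok].T), out_grid.shape)
            np.maximum.at(acc.ravel(), lin, vals[ok])
            np.add.at(wacc.ravel(), lin, 1.0)
        else:
            _trilinear_scatter(acc, wacc, idx_f, vals)

    if reducer == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.where(wacc > 0, acc / wacc, 0.0)
    return Volume(data=acc, grid=out_grid), wacc


def transforms_to_frame(transforms, converged=None) -> pd.DataFrame:
    """Serialise per-frame transforms to a tidy table."""
    rows = []
    for k, tr in enumerate(transforms):
        ok = True if converged is None else bool(converged[k])
        rows.append((k, *tr.translation, *tr.rotation_deg, ok))
    return pd.DataFrame(
        rows,
        columns=["frame_index", "tx_mm", "ty_mm", "tz_mm",
                 "rx_deg", "ry_deg", "rz_deg", "converged"],
    )
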