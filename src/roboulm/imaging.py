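"""Image-domain forward model for a virtual matrix-array probe.

Volumes are formed by splatting each point scatterer as an anisotropic
Gaussian blob with the point-spread-function FWHMs, plus additive Gaussian
noise, on a regular probe-frame voxel grid.  This image-domain surrogate
replaces RF-level physics (pulse sequencing, sub-aperture reception,
nonlinear bubble echoes); a toy delay-and-sum round trip on a handful of
point targets is provided for cross-checking the geometry.

Probe frame: x = lateral, y = elevational, z = depth (positive away from the
probe).  Voxel indices are 0-based with positions at voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .scene import PhantomScene

__all__ = [
    "ProbeModel",
    "VolumeGrid",
    "Volume",
    "PSFModel",
    "voxel_pitch_two_wavelengths",
    "default_psf",
    "render_bmode",
    "render_contrast",
    "acquire_sequence",
    "das_point_roundtrip",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class ProbeModel:
    """Virtual 2D matrix array with a probe-frame pose in world coordinates."""

    aperture_mm: tuple[float, float] = (9.6, 10.6)      # lateral x elevational
    n_elements: tuple[int, int] = (32, 32)
    center_frequency_mhz: float = 7.8
    sound_speed_m_s: float = 1540.0
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: float = 0.0   # rotation about the depth axis only
    fov_halfwidth_mm: float = 7.5
    directivity_rolloff_mm: float = 3.0

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float))
        if self.center_frequency_mhz <= 0 or self.sound_speed_m_s <= 0:
            raise ValueError("frequency and sound speed must be > 0")

    @property
    def wavelength_mm(self) -> float:
        return self.sound_speed_m_s / self.center_frequency_mhz * 1e-3

    def world_to_probe(self, points: np.ndarray) -> np.ndarray:
        """Map world-frame points (N, 3) into the probe frame."""
        a = np.deg2rad(self.rotation_deg)
        c, s = np.cos(a), np.sin(a)
        rz_inv = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
        pts = np.atleast_2d(np.asarray(points, float)) - self.position
        return pts @ rz_inv.T

    def element_positions(self) -> np.ndarray:
        """Probe-frame element centres (n_lat * n_elev, 3) at z = 0."""
        nx, ny = self.n_elements
        ax, ay = self.aperture_mm
        ex = (np.arange(nx) - (nx - 1) / 2.0) * (ax / nx)
        ey = (np.arange(ny) - (ny - 1) / 2.0) * (ay / ny)
        gx, gy = np.meshgrid(ex, ey, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])


def voxel_pitch_two_wavelengths(probe: ProbeModel) -> float:
    """Online reconstruction voxel pitch of two wavelengths, in mm."""
    return 2.0 * probe.wavelength_mm


@dataclass(frozen=True)
class VolumeGrid:
    """Regular probe-frame voxel grid, voxel-centre convention."""

    origin: np.ndarray          # mm, centre of voxel (0,0,0)
    pitch: np.ndarray           # mm per axis
    shape: tuple[int, int, int]
    frame_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        pitch = np.broadcast_to(np.asarray(self.pitch, float), (3,)).copy()
        object.__setattr__(self, "pitch", pitch)
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if np.any(pitch <= 0):
            raise ValueError("pitch must be > 0 on every axis")

    @classmethod
    def centered(cls, center, extent_mm, pitch, frame_time: float = 0.0) -> "VolumeGrid":
        """Grid of physical size ``extent_mm`` centred on ``center``."""
        center = np.asarray(center, float)
        pitch = np.broadcast_to(np.asarray(pitch, float), (3,))
        extent = np.broadcast_to(np.asarray(extent_mm, float), (3,))
        shape = np.maximum(np.round(extent / pitch).astype(int), 1)
        origin = center - (shape - 1) / 2.0 * pitch
        return cls(origin=origin, pitch=pitch, shape=tuple(shape), frame_time=frame_time)

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.pitch

    @property
    def center(self) -> np.ndarray:
        return self.origin + (np.asarray(self.shape) - 1) / 2.0 * self.pitch

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + np.arange(self.shape[i]) * self.pitch[i] for i in range(3)
        )

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.pitch

    def mm_to_index(self, pos: np.ndarray) -> np.ndarray:
        return (np.asarray(pos, float) - self.origin) / self.pitch


@dataclass(frozen=True)
class Volume:
    """3D intensity grid with physical geometry and a frame timestamp."""

    data: np.ndarray
    grid: VolumeGrid

    def __post_init__(self):
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def frame_time(self) -> float:
        return self.grid.frame_time

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, grid=self.grid)


@dataclass(frozen=True)
class PSFModel:
    """Separable Gaussian point-spread function with optional side lobes."""

    fwhm_mm: tuple[float, float, float]
    sidelobe_amplitude: float = 0.0
    sidelobe_offset_mm: float = 1.5

    def __post_init__(self):
        if np.any(np.asarray(self.fwhm_mm) <= 0):
            raise ValueError("fwhm must be > 0")
        if not (0.0 <= self.sidelobe_amplitude < 1.0):
            raise ValueError("sidelobe_amplitude must be in [0, 1)")

    @property
    def sigma_mm(self) -> np.ndarray:
        return np.asarray(self.fwhm_mm, float) * FWHM_TO_SIGMA


def default_psf(probe: ProbeModel, depth_mm: float = 20.0) -> PSFModel:
    """Diffraction-heuristic PSF: axial 2*lambda; lateral/elevational
    ``lambda * depth / aperture`` evaluated at ``depth_mm``."""
    lam = probe.wavelength_mm
    ax, ay = probe.aperture_mm
    return PSFModel(fwhm_mm=(lam * depth_mm / ax, lam * depth_mm / ay, 2.0 * lam))


def _splat(
    data: np.ndarray,
    grid: VolumeGrid,
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigma_mm: np.ndarray,
    n_sigma: float = 4.0,
) -> None:
    """Accumulate Gaussian blobs into ``data`` (in place), windowed at n_sigma."""
    if len(positions) == 0:
        return
    axes = grid.axes()
    shape = grid.shape
    half = np.ceil(n_sigma * sigma_mm / grid.pitch).astype(int)
    idx_f = grid.mm_to_index(positions)
    for p_idx, amp in zip(idx_f, amplitudes):
        lo = np.maximum(np.ceil(p_idx - half).astype(int), 0)
        hi = np.minimum(np.floor(p_idx + half).astype(int), np.asarray(shape) - 1)
        if np.any(lo > hi):
            continue
        profs = []
        for ax in range(3):
            x = axes[ax][lo[ax]:hi[ax] + 1]
            mu = grid.origin[ax] + p_idx[ax] * grid.pitch[ax]
            profs.append(np.exp(-0.5 * ((x - mu) / sigma_mm[ax]) ** 2))
        blob = amp * profs[0][:, None, None] * profs[1][None, :, None] * profs[2][None, None, :]
        data[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += blob


def _render_points(
    positions_world: np.ndarray,
    amplitudes: np.ndarray,
    probe: ProbeModel,
    grid: VolumeGrid,
    psf: PSFModel,
) -> np.ndarray:
    """Noiseless volume from world-frame point scatterers."""
    data = np.zeros(grid.shape, dtype=float)
    if len(positions_world) == 0:
        return data
    pts = probe.world_to_probe(positions_world)
    amps = np.asarray(amplitudes, float).copy()

    # hard field-of-view mask (targets outside the FoV contribute nothing)
    fov = probe.fov_halfwidth_mm
    inside = (np.abs(pts[:, 0]) <= fov) & (np.abs(pts[:, 1]) <= fov)
    pts, amps = pts[inside], amps[inside]
    if len(pts) == 0:
        return data

    # directivity roll-off beyond the physical footprint
    half_ap = np.asarray(probe.aperture_mm) / 2.0
    excess = np.maximum(np.abs(pts[:, :2]) - half_ap, 0.0)
    w = np.exp(-0.5 * np.sum((excess / probe.directivity_rolloff_mm) ** 2, axis=1))
    amps = amps * w

    sig = psf.sigma_mm
    _splat(data, grid, pts, amps, sig)
    if psf.sidelobe_amplitude > 0:
        for side in (-1.0, 1.0):
            off = np.array([side * psf.sidelobe_offset_mm, 0.0, 0.0])
            _splat(data, grid, pts + off, amps * psf.sidelobe_amplitude, sig)
    return data


def render_bmode(
    scene: PhantomScene,
    probe: ProbeModel,
    grid: VolumeGrid,
    psf: PSFModel,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Volume:
    """B-mode volume: tissue scatterers plus bubbles, with additive noise."""
    tpos, tamp = scene.tissue_scatterers()
    bpos = scene.bubble_positions()
    pos = np.vstack([tpos, bpos]) if len(bpos) else tpos
    amp = np.concatenate([tamp, scene.bubble_amplitudes()]) if len(bpos) else tamp
    data = _render_points(pos, amp, probe, grid, psf)
    if noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng()
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return Volume(data=data, grid=grid)


def render_contrast(
    scene: PhantomScene,
    probe: ProbeModel,
    grid: VolumeGrid,
    psf: PSFModel,
    noise_sigma: float = 0.0,
    tissue_leakage: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Volume:
    """Contrast volume: bubbles only, plus a residual tissue-leakage fraction."""
    bpos = scene.bubble_positions()
    bamp = scene.bubble_amplitudes()
    data = _render_points(bpos, bamp, probe, grid, psf)
    if tissue_leakage > 0:
        tpos, tamp = scene.tissue_scatterers()
        data += _render_points(tpos, tissue_leakage * tamp, probe, grid, psf)
    if noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng()
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return Volume(data=data, grid=grid)


def acquire_sequence(
    scene_fn,
    probe_fn,
    grid: VolumeGrid,
    psf: PSFModel,
    volume_rate_hz: float,
    duration_s: float,
    render=render_bmode,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Yield frames at exactly uniform spacing ``1/volume_rate``.

    ``scene_fn(t) -> PhantomScene`` and ``probe_fn(t) -> ProbeModel`` are
    evaluated at each frame time, so a closed-loop pose source can drive the
    probe.  Frame count is ``floor(duration * rate)``.
    """
    if volume_rate_hz <= 0:
        raise ValueError("volume_rate must be > 0")
    n_frames = int(np.floor(duration_s * volume_rate_hz))
    for k in range(n_frames):
        t = k / volume_rate_hz
        g = replace(grid, frame_time=t)
        yield render(scene_fn(t), probe_fn(t), g, psf, noise_sigma=noise_sigma, rng=rng)


def das_point_roundtrip(
    targets,
    probe: ProbeModel,
    grid: VolumeGrid,
    pulse_sigma_mm: float = 0.3,
    element_stride: int = 2,
) -> Volume:
    """Toy plane-wave transmit / delay-and-sum receive on point targets.

    Per-element received signals are Gaussian pulses at the two-way time of
    flight (non-steered plane-wave transmit: down-going delay ``z/c``; receive
    delay = target-to-element distance / c).  Beamforming sums, for each
    voxel, the element signals evaluated at the voxel's expected delays.
    ``element_stride`` subsamples the 32 x 32 aperture to keep the toy cheap.
    """
    targets = np.atleast_2d(np.asarray(targets, float))
    if len(targets) > 10:
        raise ValueError("toy DAS supports at most 10 point targets")
    if np.prod(grid.shape) > 64**3:
        raise ValueError("toy DAS grid limited to 64^3 voxels")
    if np.any(targets[:, 2] <= 0):
        raise ValueError("targets must be in front of the array (z > 0)")

    elems = probe.element_positions()[:: max(1, element_stride)]
    ax, ay, az = grid.axes()
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
    vox = np.stack([gx, gy, gz], axis=-1)  # (nx, ny, nz, 3)

    data = np.zeros(grid.shape, dtype=float)
    # work in distance units (delay * c); pulse width expressed in mm
    for e in elems:
        # expected round-trip path length for each voxel
        d_vox = vox[..., 2] + np.linalg.norm(vox - e, axis=-1)
        for tgt in targets:
            d_tgt = tgt[2] + np.linalg.norm(tgt - e)
            data += np.exp(-0.5 * ((d_vox - d_tgt) / pulse_sigma_mm) ** 2)
    return Volume(data=data, grid=grid)
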