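"""Synthetic crossed-channel phantom scene and its rigid / flow dynamics.

The phantom emulates a wall-less microvasculature flow phantom: two straight
cylindrical channels (default lumen diameter 200 um) crossing at a shallow
angle at ~20 mm depth, a 1 mm landmark ball with two supporting lobes used by
the tracking loop, diffuse tissue speckle scatterers, and microbubbles
advected through the channels with a parabolic (Poiseuille) velocity profile.

World frame: x = lateral, y = elevational, z = depth (mm).  At time zero the
probe frame coincides with the world frame.  Rigid phantom motion along a
stage :class:`~roboulm.kinematics.MotionProfile` displaces every scene point
by the same vector; bubbles are additionally advected along their channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinematics import MotionProfile

__all__ = ["Channel", "BubbleState", "PhantomScene", "default_scene", "scene_at_time"]


@dataclass(frozen=True)
class Channel:
    """Straight cylindrical channel given by its axis segment and radius."""

    p0: np.ndarray  # axis start, mm
    p1: np.ndarray  # axis end, mm
    radius: float   # lumen radius, mm

    def __post_init__(self):
        object.__setattr__(self, "p0", np.asarray(self.p0, float))
        object.__setattr__(self, "p1", np.asarray(self.p1, float))
        if self.radius <= 0:
            raise ValueError("channel radius must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def direction(self) -> np.ndarray:
        return (self.p1 - self.p0) / self.length

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Two unit vectors orthogonal to the axis (radial basis)."""
        u = self.direction
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(u, helper)) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        n1 = np.cross(u, helper)
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(u, n1)
        return n1, n2

    def point(self, s, r, phi) -> np.ndarray:
        """World position at arc length ``s``, radial offset ``r``, azimuth ``phi``."""
        n1, n2 = self.frame()
        s = np.asarray(s, float)
        off = np.multiply.outer(r * np.cos(phi), n1) + np.multiply.outer(r * np.sin(phi), n2)
        return self.p0 + np.multiply.outer(s, self.direction) + off


@dataclass(frozen=True)
class BubbleState:
    """Microbubble inside a channel, parameterised in channel coordinates."""

    channel_id: int
    s: float        # arc length along the axis, mm
    r: float        # radial offset from the axis, mm
    phi: float      # azimuth of the radial offset, rad
    amplitude: float


@dataclass(frozen=True)
class PhantomScene:
    """Time-zero geometry of the phantom in the world frame."""

    channels: tuple[Channel, ...]
    landmark_center: np.ndarray
    landmark_radius: float
    landmark_scatterers: np.ndarray      # (N, 3) positions filling the ball
    landmark_amplitude: float
    lobe_scatterers: np.ndarray          # (M, 3) supporting-structure points
    lobe_amplitude: float
    speckle_positions: np.ndarray        # (K, 3)
    speckle_amplitudes: np.ndarray       # (K,)
    bubbles: tuple[BubbleState, ...]
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "landmark_center", np.asarray(self.landmark_center, float))
        for b in self.bubbles:
            ch = self.channels[b.channel_id]
            if b.r > ch.radius + 1e-12:
                raise ValueError("bubble radial offset exceeds channel radius")
        if len(self.channels) == 2:
            d = _segment_distance(self.channels[0], self.channels[1])
            rmax = max(c.radius for c in self.channels)
            if d > rmax + 1e-9:
                raise ValueError(
                    "channels do not cross: axis separation "
                    f"{d:.3g} mm exceeds one radius"
                )

    def bubble_positions(self) -> np.ndarray:
        """(B, 3) world positions of all bubbles."""
        if not self.bubbles:
            return np.zeros((0, 3))
        return np.array(
            [self.channels[b.channel_id].point(b.s, b.r, b.phi) for b in self.bubbles]
        )

    def bubble_amplitudes(self) -> np.ndarray:
        return np.array([b.amplitude for b in self.bubbles])

    def tissue_scatterers(self) -> tuple[np.ndarray, np.ndarray]:
        """All non-bubble scatterers: (positions (N,3), amplitudes (N,))."""
        pos = np.vstack([
            self.landmark_scatterers,
            self.lobe_scatterers,
            self.speckle_positions,
        ])
        amp = np.concatenate([
            np.full(len(self.landmark_scatterers), self.landmark_amplitude),
            np.full(len(self.lobe_scatterers), self.lobe_amplitude),
            self.speckle_amplitudes,
        ])
        return pos, amp

    def translated(self, dvec: np.ndarray) -> "PhantomScene":
        """Scene rigidly displaced by ``dvec`` (bubble channel coords unchanged)."""
        dvec = np.asarray(dvec, float)
        return replace(
            self,
            channels=tuple(
                Channel(c.p0 + dvec, c.p1 + dvec, c.radius) for c in self.channels
            ),
            landmark_center=self.landmark_center + dvec,
            landmark_scatterers=self.landmark_scatterers + dvec,
            lobe_scatterers=self.lobe_scatterers + dvec,
            speckle_positions=self.speckle_positions + dvec,
        )

    def to_table(self) -> pd.DataFrame:
        """Scatterer table (x_mm, y_mm, z_mm, amplitude, kind)."""
        rows = []
        for name, pos, amp in [
            ("landmark", self.landmark_scatterers,
             np.full(len(self.landmark_scatterers), self.landmark_amplitude)),
            ("lobe", self.lobe_scatterers,
             np.full(len(self.lobe_scatterers), self.lobe_amplitude)),
            ("speckle", self.speckle_positions, self.speckle_amplitudes),
            ("bubble", self.bubble_positions(), self.bubble_amplitudes()),
        ]:
            for p, a in zip(pos, amp):
                rows.append((p[0], p[1], p[2], a, name))
        return pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "amplitude", "kind"])


def _segment_distance(a: Channel, b: Channel) -> float:
    """Minimum distance between the two channel axis segments."""
    p, u = a.p0, a.p1 - a.p0
    q, v = b.p0, b.p1 - b.p0
    w = p - q
    uu, uv, vv = u @ u, u @ v, v @ v
    uw, vw = u @ w, v @ w
    den = uu * vv - uv * uv
    if den < 1e-12:
        s = 0.0
    else:
        s = np.clip((uv * vw - vv * uw) / den, 0.0, 1.0)
    t = np.clip((uv * s + vw) / vv, 0.0, 1.0) if vv > 0 else 0.0
    s = np.clip((uv * t - uw) / uu, 0.0, 1.0) if uu > 0 else 0.0
    return float(np.linalg.norm(w + s * u - t * v))


def _fill_ball(center, radius, spacing) -> np.ndarray:
    """Regular grid of points inside a ball (deterministic landmark fill)."""
    n = int(np.ceil(radius / spacing))
    ax = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return pts + np.asarray(center, float)


def _fill_ellipsoid(center, semiaxes, spacing) -> np.ndarray:
    semiaxes = np.asarray(semiaxes, float)
    n = np.ceil(semiaxes / spacing).astype(int)
    axes = [np.arange(-k, k + 1) * spacing for k in n]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.sum((pts / semiaxes) ** 2, axis=1) <= 1.0]
    return pts + np.asarray(center, float)


def default_scene(
    seed: int = 0,
    n_speckle: int = 400,
    n_bubbles: int = 20,
    channel_radius: float = 0.1,
    crossing_angle_deg: float = 30.0,
    channel_depth: float = 20.0,
    channel_half_length: float = 8.0,
    landmark_center=(0.0, 2.5, 20.0),
    landmark_radius: float = 0.5,
    landmark_amplitude: float = 30.0,
    speckle_amplitude: float = 1.0,
    bubble_amplitude: float = 10.0,
    speckle_box=((-8.0, 8.0), (-8.0, 8.0), (14.0, 26.0)),
) -> PhantomScene:
    """Construct the default crossed-channel phantom.

    The two channels lie in the plane z = ``channel_depth`` (with a +-0.05 mm
    depth stagger so they pass within one radius rather than colliding),
    crossing at ``crossing_angle_deg`` centred at (0, -1, depth).  The 1 mm
    landmark ball sits above the channels with two ellipsoidal supporting
    lobes flanking it laterally.
    """
    rng = np.random.default_rng(seed)
    half = np.deg2rad(crossing_angle_deg / 2.0)
    cross_center = np.array([0.0, -1.0, channel_depth])
    channels = []
    for k, (ang, dz) in enumerate([(half, +0.05), (-half, -0.05)]):
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        p0 = cross_center - channel_half_length * u + np.array([0, 0, dz])
        p1 = cross_center + channel_half_length * u + np.array([0, 0, dz])
        channels.append(Channel(p0, p1, channel_radius))

    landmark_center = np.asarray(landmark_center, float)
    landmark_pts = _fill_ball(landmark_center, landmark_radius, spacing=0.25)
    lobes = np.vstack([
        _fill_ellipsoid(landmark_center + np.array([-1.5, 0.0, 0.3]),
                        (0.6, 0.3, 0.3), spacing=0.25),
        _fill_ellipsoid(landmark_center + np.array([1.5, 0.0, 0.3]),
                        (0.6, 0.3, 0.3), spacing=0.25),
    ])

    (x0, x1), (y0, y1), (z0, z1) = speckle_box
    speckle_pos = rng.uniform([x0, y0, z0], [x1, y1, z1], size=(n_speckle, 3))
    # Rayleigh amplitudes emulate fully developed speckle statistics
    speckle_amp = speckle_amplitude * rng.rayleigh(scale=1.0, size=n_speckle)

    bubbles = []
    for _ in range(n_bubbles):
        cid = int(rng.integers(0, len(channels)))
        ch = channels[cid]
        s = float(rng.uniform(0.0, ch.length))
        r = channel_radius * float(np.sqrt(rng.uniform()))  # uniform over the disc
        phi = float(rng.uniform(0.0, 2 * np.pi))
        bubbles.append(BubbleState(cid, s, r, phi, bubble_amplitude))

    return PhantomScene(
        channels=tuple(channels),
        landmark_center=landmark_center,
        landmark_radius=landmark_radius,
        landmark_scatterers=landmark_pts,
        landmark_amplitude=landmark_amplitude,
        lobe_scatterers=lobes,
        lobe_amplitude=landmark_amplitude * 0.6,
        speckle_positions=speckle_pos,
        speckle_amplitudes=speckle_amp,
        bubbles=tuple(bubbles),
        seed=seed,
    )


def scene_at_time(
    scene: PhantomScene,
    profile: MotionProfile | None,
    t: float,
    flow_speed: float = 1.0,
) -> PhantomScene:
    """Scene at time ``t``: rigid stage displacement plus bubble advection.

    Bubbles follow a parabolic Poiseuille profile: axial speed
    ``2 * flow_speed * (1 - (r/R)**2)`` where ``flow_speed`` is the mean
    cross-sectional speed (mm/s).  A bubble whose arc length exceeds the
    channel length is recycled at the inlet with a fresh radial position drawn
    from an RNG keyed on the scene seed, bubble index and lap count, so the
    dynamics are a pure (deterministic) function of time.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    new_bubbles = []
    for i, b in enumerate(scene.bubbles):
        ch = scene.channels[b.channel_id]
        L = ch.length
        s, r, phi = b.s, b.r, b.phi
        t_left = float(t)
        lap = 0
        # advance lap by lap so each recycling re-draws the radial position
        while True:
            v = 2.0 * flow_speed * (1.0 - (r / ch.radius) ** 2)
            if v <= 0:  # wall-touching bubble never moves
                break
            t_exit = (L - s) / v
            if t_exit > t_left:
                s = s + v * t_left
                break
            t_left -= t_exit
            lap += 1
            rng = np.random.default_rng([scene.seed, 7919, i, lap])
            s = 0.0
            r = ch.radius * float(np.sqrt(rng.uniform(0.0, 0.999)))
            phi = float(rng.uniform(0.0, 2 * np.pi))
        new_bubbles.append(BubbleState(b.channel_id, s, r, phi, b.amplitude))

    out = replace(scene, bubbles=tuple(new_bubbles))
    if profile is not None:
        out = out.translated(profile.displacement_vec(t))
    return out
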