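"""Residual-motion evaluation of a tracked sequence.

After closed-loop tracking, the landmark still moves inside the field of
view because of processing delays.  The evaluation localises the landmark by
weighted centroiding on the fine (0.1 mm) reconstruction, builds the
per-frame displacement series relative to the first frame (lateral +
elevational components), flags the frames between motion onset and offset
(displacement magnitude exceeding a 0.1 mm threshold), and summarises the
in-motion displacement magnitudes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imaging import Volume

__all__ = [
    "weighted_centroid",
    "displacement_series",
    "detect_onset",
    "residual_stats",
    "regress_residual_vs_speed",
]

ONSET_THRESHOLD_MM = 0.1


def weighted_centroid(volume: Volume, roi_mm=None, subtract_floor: bool = True) -> np.ndarray:
    """Intensity-weighted centroid (mm) over a physical ROI box.

    ``roi_mm`` is ((x0, x1), (y0, y1), (z0, z1)) in mm; ``None`` uses the full
    volume.  The ROI minimum is subtracted first (background floor) so that a
    uniform offset does not bias the centroid.
    """
    g = volume.grid
    if roi_mm is None:
        lo = np.zeros(3, int)
        hi = np.asarray(g.shape)
    else:
        roi = np.asarray(roi_mm, float)
        lo = np.ceil(g.mm_to_index(roi[:, 0]) - 1e-9).astype(int)
        hi = np.floor(g.mm_to_index(roi[:, 1]) + 1e-9).astype(int) + 1
        lo = np.clip(lo, 0, np.asarray(g.shape))
        hi = np.clip(hi, 0, np.asarray(g.shape))
        if np.any(hi <= lo):
            raise ValueError("ROI does not intersect the volume")
    sub = volume.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
    if subtract_floor:
        sub = sub - sub.min()
    total = sub.sum()
    if total <= 0:
        raise ValueError("ROI has no positive intensity")
    idx = np.stack(np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                               indexing="ij"))
    com = np.array([(idx[i] * sub).sum() for i in range(3)]) / total
    return g.index_to_mm(com)


def displacement_series(times_s, positions_mm, axes=(0, 1)) -> pd.DataFrame:
    """Per-frame displacement relative to the first frame.

    ``axes`` selects the components entering the magnitude (default lateral +
    elevational).  The in-motion flag is filled in by :func:`detect_onset`.
    """
    times_s = np.asarray(times_s, float)
    pos = np.asarray(positions_mm, float)
    disp = pos - pos[0]
    mag = np.linalg.norm(disp[:, list(axes)], axis=1)
    return pd.DataFrame(dict(
        t_s=times_s,
        dx_mm=disp[:, 0], dy_mm=disp[:, 1], dz_mm=disp[:, 2],
        displacement_mm=mag,
        in_motion=False,
    ))


def detect_onset(series: pd.DataFrame, threshold_mm: float = ONSET_THRESHOLD_MM) -> pd.DataFrame:
    """Flag frames between the first and last threshold exceedance.

    Returns a copy of the series with ``in_motion`` set; the onset time is
    available as the first flagged frame.  If the displacement never exceeds
    the threshold, no frame is flagged (no-motion result).
    """
    if threshold_mm <= 0:
        raise ValueError("threshold must be > 0")
    out = series.copy()
    exceed = np.flatnonzero(out["displacement_mm"].to_numpy() > threshold_mm)
    out["in_motion"] = False
    if len(exceed):
        out.loc[out.index[exceed[0]]:out.index[exceed[-1]], "in_motion"] = True
    return out


def motion_onset_time(series: pd.DataFrame) -> float | None:
    flagged = series[series["in_motion"]]
    return None if flagged.empty else float(flagged["t_s"].iloc[0])


def residual_stats(series: pd.DataFrame) -> dict:
    """Mean/std of in-motion displacement magnitude, plus a CDF helper."""
    mags = series.loc[series["in_motion"], "displacement_mm"].to_numpy()
    if len(mags) == 0:
        raise ValueError("no in-motion frames; run detect_onset first")

    def fraction_within(d_mm: float) -> float:
        return float(np.mean(mags < d_mm))

    return dict(
        mean_mm=float(mags.mean()),
        std_mm=float(mags.std()),
        n_frames=int(len(mags)),
        fraction_within=fraction_within,
    )


def regress_residual_vs_speed(means) -> dict:
    """OLS line through per-speed mean residuals: [(speed, mean_mm), ...]."""
    pts = np.asarray(means, float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two speed levels")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("speeds must not be identical")
    slope, intercept = np.polyfit(x, y, 1)
    return dict(slope=float(slope), intercept=float(intercept))
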