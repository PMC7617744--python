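"""Fourier shell correlation (FSC) resolution analysis.

Two half-data reconstructions (tracks split by index parity) are compared
shell by shell in Fourier space; the resolution is the inverse of the first
frequency at which the correlation drops below the 1/2-bit information
threshold of van Heel & Schatz,

    T(n) = (0.2071 + 1.9102 / sqrt(n)) / (1.2071 + 0.9102 / sqrt(n)),

where ``n`` is the number of voxels in the shell.  Requires a cubic grid
with isotropic pitch; the resolution search is bounded at the grid Nyquist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import Volume, VolumeGrid
from .ulm import accumulate_maps

__all__ = [
    "FSCCurve",
    "FSCResolution",
    "split_odd_even",
    "fsc_curve",
    "halfbit_threshold",
    "fsc_resolution",
]


@dataclass(frozen=True)
class FSCCurve:
    shell_freq_cyc_mm: np.ndarray   # shell centre frequencies, cycles/mm
    correlation: np.ndarray         # real normalised cross-spectral sum
    n_voxels: np.ndarray            # voxels per shell
    threshold: np.ndarray           # 1/2-bit values per shell
    defined: np.ndarray             # False where a shell had zero energy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(
            freq_cyc_per_mm=self.shell_freq_cyc_mm,
            correlation=self.correlation,
            n_voxels=self.n_voxels,
            threshold=self.threshold,
            defined=self.defined,
        ))


@dataclass(frozen=True)
class FSCResolution:
    resolution_um: float
    crossed: bool   # False: never fell below threshold (better than Nyquist)


def split_odd_even(tracks, grid: VolumeGrid, volume_rate_hz: float | None = None):
    """Accumulate two density maps from odd- and even-indexed trajectories."""
    tracks = list(tracks)
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks to split")
    maps_a = accumulate_maps(tracks[0::2], grid, volume_rate_hz)
    maps_b = accumulate_maps(tracks[1::2], grid, volume_rate_hz)
    return maps_a, maps_b


def halfbit_threshold(n_voxels) -> np.ndarray:
    """1/2-bit information threshold per shell; -> 0.2071/1.2071 as n -> inf."""
    n = np.asarray(n_voxels, float)
    if np.any(n < 1):
        raise ValueError("shell voxel counts must be >= 1")
    rn = np.sqrt(n)
    return (0.2071 + 1.9102 / rn) / (1.2071 + 0.9102 / rn)


def fsc_curve(vol_a: Volume, vol_b: Volume) -> FSCCurve:
    """Per-shell normalised cross-correlation of the two volumes' spectra.

    Shell width is one frequency bin of the FFT grid; voxels are assigned to
    the nearest-integer frequency radius.  Shells with zero energy in either
    volume are flagged undefined.
    """
    if vol_a.grid.shape != vol_b.grid.shape or not np.allclose(
        vol_a.grid.pitch, vol_b.grid.pitch
    ):
        raise ValueError("volumes must share grid geometry")
    shape = vol_a.grid.shape
    pitch = vol_a.grid.pitch
    if len(set(shape)) != 1 or np.ptp(pitch) > 1e-12:
        raise ValueError("FSC requires a cubic grid with isotropic pitch")
    n = shape[0]
    d = float(pitch[0])
    df = 1.0 / (n * d)                      # cycles/mm per frequency bin

    fa = np.fft.fftn(vol_a.data)
    fb = np.fft.fftn(vol_b.data)
    freqs = np.fft.fftfreq(n, d=d)
    fx, fy, fz = np.meshgrid(freqs, freqs, freqs, indexing="ij")
    radius = np.sqrt(fx**2 + fy**2 + fz**2) / df
    shell_idx = np.round(radius).astype(int)
    n_shells = n // 2 + 1                   # up to and including Nyquist
    sel = shell_idx < n_shells
    idx = shell_idx[sel].ravel()

    cross = np.bincount(idx, weights=(fa * np.conj(fb)).real[sel].ravel(),
                        minlength=n_shells)
    pa = np.bincount(idx, weights=(np.abs(fa) ** 2)[sel].ravel(), minlength=n_shells)
    pb = np.bincount(idx, weights=(np.abs(fb) ** 2)[sel].ravel(), minlength=n_shells)
    counts = np.bincount(idx, minlength=n_shells)

    defined = (pa > 0) & (pb > 0) & (counts > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(defined, cross / np.sqrt(pa * pb), np.nan)
    return FSCCurve(
        shell_freq_cyc_mm=np.arange(n_shells) * df,
        correlation=corr,
        n_voxels=counts,
        threshold=halfbit_threshold(np.maximum(counts, 1)),
        defined=defined,
    )


def fsc_resolution(curve: FSCCurve) -> FSCResolution:
    """Resolution (um) at the first sub-threshold crossing, DC excluded.

    Linear interpolation locates the crossing frequency between the
    bracketing shells.  If the curve never falls below its threshold the
    result carries ``crossed=False`` with the grid-Nyquist wavelength as a
    "better than" bound.
    """
    freq = curve.shell_freq_cyc_mm
    if len(freq) < 3:
        raise ValueError("curve must have at least 3 shells")
    corr = curve.correlation
    thr = curve.threshold
    for k in range(1, len(freq)):          # skip DC
        if not curve.defined[k]:
            continue
        if corr[k] < thr[k]:
            # interpolate between previous defined shell and this one
            j = k - 1
            while j > 0 and not curve.defined[j]:
                j -= 1
            d_prev = corr[j] - thr[j]
            d_here = corr[k] - thr[k]
            if d_prev <= 0 or j == 0 or j == k:
                # no usable bracket (or it would interpolate through DC)
                f_cross = freq[k]
            else:
                frac = d_prev / (d_prev - d_here)
                f_cross = freq[j] + frac * (freq[k] - freq[j])
            return FSCResolution(resolution_um=1.0 / f_cross * 1e3, crossed=True)
    f_nyq = freq[-1]
    return FSCResolution(resolution_um=1.0 / f_nyq * 1e3, crossed=False)
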