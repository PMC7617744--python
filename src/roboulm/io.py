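"""File I/O: volumes as NIfTI or multi-page TIFF, tables as CSV.

NIfTI affines carry the voxel pitch and physical origin (mm); TIFF output
writes the pitch and origin to a JSON sidecar since the format has no
standard 3D geometry header.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .imaging import Volume, VolumeGrid

__all__ = ["save_volume", "load_volume", "save_volume_sequence"]


def save_volume(volume: Volume, path) -> None:
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(volume.grid.pitch)
        affine[:3, 3] = volume.grid.origin
        img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
        img.header["pixdim"][4] = 0.0
        nib.save(img, str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), volume.data.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(dict(
            origin_mm=list(volume.grid.origin),
            pitch_mm=list(volume.grid.pitch),
            frame_time_s=volume.grid.frame_time,
        )))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def load_volume(path) -> Volume:
    path = Path(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
        grid = VolumeGrid(origin=affine[:3, 3], pitch=np.diag(affine[:3, :3]),
                          shape=data.shape)
        return Volume(data=data, grid=grid)
    if path.suffix in (".tif", ".tiff"):
        data = tifffile.imread(str(path)).astype(float)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else dict(
            origin_mm=[0, 0, 0], pitch_mm=[1, 1, 1], frame_time_s=0.0)
        grid = VolumeGrid(origin=meta["origin_mm"], pitch=meta["pitch_mm"],
                          shape=data.shape, frame_time=meta.get("frame_time_s", 0.0))
        return Volume(data=data, grid=grid)
    raise ValueError(f"unsupported volume format: {path}")


def save_volume_sequence(frames, directory, prefix: str, fmt: str = "nii") -> list[Path]:
    """Write an ordered frame sequence as prefix_0000.<fmt>, ..."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(frames):
        p = directory / f"{prefix}_{k:04d}.{fmt}"
        save_volume(frame, p)
        paths.append(p)
    return paths
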