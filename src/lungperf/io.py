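"""NIfTI reading/writing for volumes and dynamic series.

Internal arrays use (time, slice, row, col); NIfTI files store the reversed
(col, row, slice, time) axis order so that standard viewers see sensible
spatial axes. DICOM input is not supported in this build (no DICOM library
in the runtime); a clear error points users at NIfTI conversion.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .series import DynamicSeries

__all__ = ["read_series", "write_series", "read_volume", "write_volume"]


def _check_path(path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".dcm" or path.is_dir():
        raise NotImplementedError(
            "DICOM series reading is not available in this build; convert the "
            "series to a 4D NIfTI (e.g. with dcm2niix) and pass that instead"
        )
    return path


def read_series(path) -> DynamicSeries:
    """Read a 3D or 4D NIfTI file as a DynamicSeries (3D = one timepoint)."""
    img = nib.load(str(_check_path(path)))
    arr = np.asanyarray(img.dataobj, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4:
        raise ValueError(f"expected 3D/4D NIfTI, got ndim={arr.ndim}")
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(arr, (3, 2, 1, 0))  # (x,y,z,t) -> (t, slice, row, col)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return DynamicSeries(data, voxel_spacing=spacing)


def write_series(series: DynamicSeries, path) -> None:
    arr = np.transpose(series.data.astype(np.float32), (3, 2, 1, 0))
    sz, sy, sx = series.voxel_spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((sx, sy, sz, 1.0))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D NIfTI as ((slice, row, col) array, spacing)."""
    img = nib.load(str(_check_path(path)))
    arr = np.asanyarray(img.dataobj, dtype=np.float32)
    if arr.ndim == 4 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got ndim={arr.ndim}")
    zooms = img.header.get_zooms()[:3]
    return np.transpose(arr, (2, 1, 0)), (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def write_volume(volume: np.ndarray, path,
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    volume = np.asarray(volume)
    if volume.ndim == 2:
        volume = volume[None]
    if volume.ndim != 3:
        raise ValueError("write_volume expects a 2D or 3D array")
    sz, sy, sx = spacing
    arr = np.transpose(volume.astype(np.float32), (2, 1, 0))
    img = nib.Nifti1Image(arr, np.diag([sx, sy, sz, 1.0]))
    nib.save(img, str(path))
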