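"""Pre/post-processing of dynamic perfusion series.

Background subtraction of the pre-contrast baseline, peak-phase selection,
maximum intensity projection (MIP) over a slab of coronal slices and a simple
lung-mask estimator used when no ground-truth mask is available.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .series import DynamicSeries

__all__ = [
    "background_subtract",
    "auto_baseline_frames",
    "select_peak_frame",
    "compute_mip",
    "estimate_lung_mask",
]


def auto_baseline_frames(series: DynamicSeries, mask: np.ndarray | None = None) -> list[int]:
    """Frames before the first frame whose masked mean exceeds 10% of the series max.

    Falls back to frame 0 alone when enhancement starts immediately.
    """
    data = series.data
    if mask is None:
        means = data.reshape(data.shape[0], -1).mean(axis=1)
    else:
        means = np.array([v[mask].mean() for v in data])
    threshold = 0.1 * means.max()
    above = np.nonzero(means > threshold)[0]
    first = int(above[0]) if above.size else len(means)
    return list(range(first)) if first > 0 else [0]


def background_subtract(series: DynamicSeries, baseline_frames) -> DynamicSeries:
    """Subtract the mean of the baseline frames; clip negatives to zero.

    Magnitude images cannot be negative, so the subtraction is clipped at 0;
    this also makes the operation idempotent for a fixed baseline set.
    """
    frames = sorted(set(int(i) for i in baseline_frames))
    if not frames:
        raise ValueError("baseline frame set is empty")
    if max(frames) >= series.n_timepoints or min(frames) < 0:
        raise IndexError("baseline frame index out of range")
    data = series.data
    means = data.reshape(data.shape[0], -1).mean(axis=1)
    if int(np.argmax(means)) in frames:
        warnings.warn("baseline set contains the peak-enhancement frame", stacklevel=2)
    baseline = data[frames].mean(axis=0)
    out = np.clip(data - baseline[None], 0.0, None)
    return DynamicSeries(out, voxel_spacing=series.voxel_spacing,
                         time_index_of_baseline=max(frames))


def select_peak_frame(series: DynamicSeries, mask: np.ndarray) -> int:
    """Timepoint with maximal mean intensity inside ``mask`` (earliest on ties)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    means = np.array([v[mask].mean() for v in series.data])
    if np.all(means == 0):
        raise ValueError("no enhancement detected: series is all zero in the mask")
    return int(np.argmax(means))


def compute_mip(volume: np.ndarray, slab: tuple[int, int] | None = None) -> np.ndarray:
    """Maximum intensity projection across a slab of slices.

    ``slab`` is a half-open ``(start, stop)`` range on the slice axis;
    ``None`` projects through the whole volume.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("compute_mip expects a 3D (slice, row, col) volume")
    if slab is None:
        slab = (0, volume.shape[0])
    start, stop = slab
    if start < 0 or stop > volume.shape[0] or stop <= start:
        raise ValueError(f"empty or out-of-bounds slab {slab}")
    return volume[start:stop].max(axis=0)


def default_mip_slab(mask: np.ndarray, n_slices: int = 20) -> tuple[int, int]:
    """Slab of ``n_slices`` centred on the lung mask's slice-axis centroid."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError("mask is empty")
    centre = int(round(idx.mean()))
    half = n_slices // 2
    start = max(0, centre - half)
    stop = min(mask.shape[0], start + n_slices)
    start = max(0, stop - n_slices)
    return start, stop


def estimate_lung_mask(volume: np.ndarray) -> np.ndarray:
    """Lung mask from a background-subtracted peak-phase enhancement volume.

    Otsu threshold on noise-suppressed, log-compressed intensities (log
    compression keeps the vessel/parenchyma gap from dominating the
    histogram), a one-voxel in-plane erosion to strip the blur rim the
    smoothing adds around the lungs, morphological closing, then retention
    of the largest connected components (up to two, one per lung).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("estimate_lung_mask expects a 3D volume")
    finite = np.clip(volume, 0.0, None)
    if finite.max() <= 0:
        raise ValueError("empty mask: volume contains no enhancement")
    # suppress noise before thresholding: the clipped background-noise tail
    # otherwise overlaps the parenchymal enhancement mode
    smoothed = ndimage.gaussian_filter(finite, sigma=(0, 1.5, 1.5), mode="nearest")
    logv = np.log1p(smoothed)
    mask = logv > threshold_otsu(logv)
    in_plane = np.zeros((1, 3, 3), dtype=bool)
    in_plane[0] = True
    mask = ndimage.binary_erosion(mask, structure=in_plane)
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3), dtype=bool))
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty mask after morphological processing")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    keep = [order[0] + 1]
    if len(order) > 1 and sizes[order[1]] >= 0.2 * sizes[order[0]]:
        keep.append(order[1] + 1)
    mask = np.isin(labels, keep)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise ValueError("empty mask after morphological processing")
    return mask
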