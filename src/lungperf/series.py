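"""Core containers for dynamic perfusion series and 2D working images.

The whole package uses a single axis convention for dynamic data:
``(time, slice, row, col)``, 0-based, with slices being coronal planes.
Single volumes are ``(slice, row, col)`` and network inputs are 2D
``(row, col)`` coronal slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DynamicSeries", "NoisyImage"]


@dataclass
class DynamicSeries:
    """A 4D dynamic contrast-enhanced series.

    Parameters
    ----------
    data
        Array of shape ``(time, slice, row, col)``. Acquired magnitude data
        are non-negative; synthetic noisy series may contain small negative
        excursions because the simulated noise is zero-mean additive.
    voxel_spacing
        ``(slice, row, col)`` spacing in millimetres.
    time_index_of_baseline
        Optional index of the last pre-contrast frame, if known.
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    time_index_of_baseline: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError(
                f"DynamicSeries requires (time, slice, row, col) data, got ndim={self.data.ndim}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("DynamicSeries requires at least one timepoint")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DynamicSeries data must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def volume(self, t: int) -> np.ndarray:
        """The 3D volume at timepoint ``t``."""
        return self.data[t]


@dataclass
class NoisyImage:
    """A single 2D noisy perfusion slice, the ``y`` of the restoration problem."""

    pixels: np.ndarray
    provenance: tuple = field(default=("unknown", -1, -1))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("NoisyImage must be 2D")
        if min(self.pixels.shape) < 16:
            raise ValueError("NoisyImage must be at least 16x16")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("NoisyImage must be finite")
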