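"""Gridded density containers with physical calibration.

Conventions used throughout the package:

* 3D arrays are indexed ``(z, y, x)`` (numpy order); the tomographic thin
  axis (beam direction) is ``z`` (axis 0) and the tilt axis is ``y``
  (axis 1).
* 2D images are indexed ``(row, col) = (y, x)``; after projection and
  rotation the filament long axis lies along the image ``y`` axis
  (axis 0), so axial frequency in a power spectrum runs along rows.
* Pixel/voxel coordinates are 0-based with voxel centers at integer
  positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DensityVolume:
    """A 3D density map with an isotropic voxel size in Å per pixel."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Image2D:
    """A 2D image with a pixel size in Å per pixel."""

    data: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {self.data.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape
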