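"""Bone segmentation: HU thresholding and virtual tissue dissection.

Reduces an HU volume to the bony structures the way a clinical workstation
does before 3D model export: a global Hounsfield threshold followed by
keeping the dominant connected component (the "virtual tissue dissection"
that discards disconnected specks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import VoxelVolume

__all__ = ["BoneMask", "threshold_bone", "largest_component", "DEFAULT_BONE_HU_MIN"]

#: default lower HU bound for bone; cortical bone is well above, soft tissue well below.
DEFAULT_BONE_HU_MIN = 300.0


@dataclass(frozen=True)
class BoneMask:
    """Binary bone occupancy grid sharing shape and spacing with its source volume."""

    values: np.ndarray  # (nx, ny, nz) bool
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.dtype != bool:
            raise ValueError("mask must be a 3D boolean array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive numbers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.values.sum())


def threshold_bone(volume: VoxelVolume, hu_min: float = DEFAULT_BONE_HU_MIN) -> BoneMask:
    """Mark every voxel with HU >= ``hu_min`` as bone."""
    if not math.isfinite(hu_min):
        raise ValueError("hu_min must be finite")
    return BoneMask(values=volume.values >= hu_min, spacing=volume.spacing)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_component(mask: BoneMask, connectivity: int = 26) -> BoneMask:
    """Keep only the largest connected bone component.

    Size ties are broken in favour of the component containing the
    lexicographically smallest voxel index, which with scipy's raster-order
    labelling is the lowest label id.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6 or 26")
    if not mask.values.any():
        raise ValueError("cannot dissect an empty bone mask")
    labels, n = ndimage.label(mask.values, structure=_STRUCTURES[connectivity])
    if n == 1:
        return mask
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = int(np.argmax(sizes)) + 1  # argmax returns the first (lowest) label on ties
    return BoneMask(values=labels == best, spacing=mask.spacing)
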