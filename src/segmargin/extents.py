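"""Ellipsoid-formula volume estimation from maximal orthogonal extents.

Clinical practice often estimates a lesion volume from its maximum
diameters in the three canonical imaging planes (transverse, coronal,
sagittal) via the ellipsoid formula

    V = length x width x height x 0.52

with 0.52 approximating pi/6 ~ 0.5236.  This module measures the extents
on a binary VOI along the lattice axes (no oriented-bounding-box fit) and
applies the formula, for comparison against the true voxel-count volume.

Extent convention: full voxel width, (max index - min index + 1) x
spacing, so a single voxel has extent one voxel rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import BinaryMask, MM3_PER_ML

__all__ = ["ExtentTriple", "max_extents", "ellipsoid_volume_ml", "ELLIPSOID_FACTOR"]

#: the clinical ellipsoid-formula constant (approximates pi/6)
ELLIPSOID_FACTOR = 0.52


@dataclass(frozen=True)
class ExtentTriple:
    """Maximal VOI extent (mm) along the three canonical axes."""

    length_mm: float
    width_mm: float
    height_mm: float

    def __iter__(self):
        yield self.length_mm
        yield self.width_mm
        yield self.height_mm


def max_extents(mask: BinaryMask) -> ExtentTriple:
    """Full-voxel-width extent of the VOI along each lattice axis."""
    if mask.is_empty():
        raise ValueError("extents undefined for an empty mask")
    extents = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = mask.data.any(axis=other)
        idx = np.flatnonzero(profile)
        extents.append((idx[-1] - idx[0] + 1) * mask.spacing[axis])
    return ExtentTriple(*extents)


def ellipsoid_volume_ml(extents: ExtentTriple) -> float:
    """Ellipsoid-formula volume estimate, mL: L x W x H x 0.52 / 1000."""
    l, w, h = tuple(extents)
    if l <= 0 or w <= 0 or h <= 0:
        raise ValueError(f"extents must be positive, got {(l, w, h)}")
    return l * w * h * ELLIPSOID_FACTOR / MM3_PER_ML
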