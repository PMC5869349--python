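"""Voxel-grid data model and NIfTI I/O.

All analyses in this package operate on binary volumes of interest (VOIs)
and scalar PET-like images living on a common regular, axis-aligned,
possibly anisotropic voxel grid.  The data model is deliberately minimal:
a 3D lattice (axis order x, y, z), a per-axis spacing in millimetres, and
a world origin (the mm position of the centre of voxel (0, 0, 0)).  World
coordinates follow the voxel-centre convention::

    world_mm = origin + index * spacing

Binary set operations require *compatible* grids (identical shape, spacing
and origin); nothing is resampled silently.  An explicit nearest-neighbour
resampler is provided for deliberate regridding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np

__all__ = [
    "BinaryMask",
    "ScalarImage",
    "SegmentationCase",
    "GridMismatchError",
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
    "mask_volume_ml",
    "resample_mask_nearest",
]

#: millimetres-cubed per millilitre; fixed unit convention for all volumes.
MM3_PER_ML = 1000.0


class GridMismatchError(ValueError):
    """Two volumes do not share shape, spacing and origin."""


def _as_triple(values: Iterable[float], name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in values)
    if len(t) != 3:
        raise ValueError(f"{name} must have exactly 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """A 3D boolean VOI on a regular grid.

    Parameters
    ----------
    data
        3D boolean array, axes ordered (x, y, z).
    spacing
        Positive voxel edge lengths in mm along each axis.
    origin
        World-mm position of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask data must be 3D, got ndim={arr.ndim}")
        object.__setattr__(self, "data", arr.astype(bool, copy=False))
        object.__setattr__(self, "spacing", _as_triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    # -- geometry -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def count(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "BinaryMask | ScalarImage") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_compatible(self, other: "BinaryMask | ScalarImage") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                "incompatible grids: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.data.shape}/{other.spacing}/{other.origin}"
            )

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        """New mask on the same grid with different voxel values."""
        return BinaryMask(data, self.spacing, self.origin)

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world-mm coordinates of voxel centres."""
        return tuple(  # type: ignore[return-value]
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def indices_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices (n, 3) -> world mm (n, 3)."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(
            self.spacing
        )


@dataclass(frozen=True)
class ScalarImage:
    """A 3D scalar image (SUV-like intensity) on a regular grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"image data must be 3D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", _as_triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "BinaryMask | ScalarImage") -> bool:
        return BinaryMask.same_grid(self, other)  # type: ignore[arg-type]


@dataclass
class SegmentationCase:
    """One analysed tumor: reference-standard truth plus candidate VOIs.

    Candidates are keyed by name (conventionally ``seg1``, ``seg2`` for the
    human readers and ``seg3`` for the PET-gradient segmentation); the
    union candidate ``seg4`` is derived downstream, not stored.
    """

    case_id: str
    truth: BinaryMask
    candidates: dict[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.truth.is_empty():
            raise ValueError(f"case {self.case_id}: truth mask is empty")
        for name, cand in self.candidates.items():
            self.truth.require_compatible(cand)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _grid_from_affine(affine: np.ndarray, path: str) -> tuple[tuple, tuple]:
    """Extract (spacing, origin) from an axis-aligned NIfTI affine.

    Oblique or rotated affines are rejected: the analysis assumes all
    volumes were registered to a common axis-aligned grid beforehand.
    Axis flips (negative diagonal) are likewise rejected to keep index ->
    world monotone increasing.
    """
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
        raise ValueError(
            f"{path}: oblique/rotated affine not supported; "
            "resample to an axis-aligned grid first"
        )
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: non-positive or flipped spacing {spacing}")
    origin = affine[:3, 3]
    return tuple(float(s) for s in spacing), tuple(float(o) for o in origin)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_mask(path: str | Path, name: str | None = None) -> BinaryMask:
    """Read a binary VOI from a NIfTI file (non-zero voxels become true)."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={arr.ndim}")
    spacing, origin = _grid_from_affine(img.affine, str(path))
    return BinaryMask(arr != 0, spacing, origin)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a 0/1 uint8 NIfTI whose header matches the grid."""
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))


def read_image(path: str | Path) -> ScalarImage:
    """Read a scalar (PET-like) volume from NIfTI."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).astype(np.float64)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={arr.ndim}")
    spacing, origin = _grid_from_affine(img.affine, str(path))
    return ScalarImage(arr, spacing, origin)


def write_image(image: ScalarImage, path: str | Path) -> None:
    img = nib.Nifti1Image(
        image.data.astype(np.float32), _affine(image.spacing, image.origin)
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Volume bookkeeping and regridding
# ---------------------------------------------------------------------------


def mask_volume_ml(mask: BinaryMask) -> float:
    """VOI volume in millilitres: true-voxel count x voxel volume / 1000."""
    return mask.count() * mask.voxel_volume_mm3 / MM3_PER_ML


def resample_mask_nearest(
    mask: BinaryMask,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> BinaryMask:
    """Nearest-neighbour resample onto an explicit target grid.

    Deliberate regridding only; all metric computations require masks that
    already share a grid.  Target voxel centres falling outside the source
    lattice become false.
    """
    spacing = _as_triple(spacing, "spacing")
    origin = _as_triple(origin, "origin")
    coords_mm = [
        origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)
    ]
    idx = [
        np.round((coords_mm[a] - mask.origin[a]) / mask.spacing[a]).astype(int)
        for a in range(3)
    ]
    valid = [
        (idx[a] >= 0) & (idx[a] < mask.shape[a]) for a in range(3)
    ]
    clipped = [np.clip(idx[a], 0, mask.shape[a] - 1) for a in range(3)]
    out = mask.data[np.ix_(clipped[0], clipped[1], clipped[2])].copy()
    out &= valid[0][:, None, None]
    out &= valid[1][None, :, None]
    out &= valid[2][None, None, :]
    return BinaryMask(out, spacing, origin)
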