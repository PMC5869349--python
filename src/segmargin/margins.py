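"""Safety-margin (contour-expansion) analysis.

A safety margin expands a treatment contour isotropically by a fixed
millimetre distance, to cover tumor extension the segmentation missed.
This module provides:

* :func:`expand` — isotropic expansion of a VOI by thresholding the
  Euclidean distance transform of its complement (distance measured from
  true-voxel centres, the same geometry used by the surface metrics);
* :func:`union_masks` — voxelwise union, the "combined" candidate built
  from all available segmentations of one tumor;
* :func:`min_coverage_margin` — the smallest margin whose expansion of a
  candidate fully contains the reference tumor volume (the directed
  truth→candidate maximum distance), returned as a continuous mm value;
* :func:`margin_report` — volumes and residual missed volume at a list of
  margins (default 5 and 10 mm) plus the minimum coverage margin.

Expansions are clipped to the lattice; a warning is emitted when the
expansion touches the grid boundary, because a clipped expansion can
understate the expanded volume.  An optional ``allowed_region`` restricts
expansion to an anatomical compartment (e.g. the gland) by intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, mask_volume_ml
from .metrics import missed_volume

__all__ = [
    "MarginReport",
    "expand",
    "union_masks",
    "min_coverage_margin",
    "margin_report",
    "DEFAULT_MARGINS_MM",
]

#: default safety margins analysed, mm
DEFAULT_MARGINS_MM: tuple[float, float] = (5.0, 10.0)


def _distance_to_mask(mask: BinaryMask) -> np.ndarray:
    """mm distance from every voxel centre to the nearest true voxel."""
    return ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing)


def expand(
    mask: BinaryMask,
    margin_mm: float,
    allowed_region: BinaryMask | None = None,
) -> BinaryMask:
    """Isotropic expansion: all voxel centres within ``margin_mm`` of the VOI.

    Implemented as a threshold on the Euclidean distance transform of the
    mask complement, so expansion and the minimum-coverage margin share
    one distance geometry.  The result is clipped to the lattice.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    if mask.is_empty():
        raise ValueError("cannot expand an empty mask")
    if margin_mm == 0:
        out = mask
    else:
        out = mask.with_data(_distance_to_mask(mask) <= margin_mm)
        _warn_if_clipped(out, margin_mm)
    if allowed_region is not None:
        mask.require_compatible(allowed_region)
        out = out.with_data(out.data & allowed_region.data)
    return out


def _warn_if_clipped(expanded: BinaryMask, margin_mm: float) -> None:
    d = expanded.data
    touches = (
        d[0].any() or d[-1].any()
        or d[:, 0].any() or d[:, -1].any()
        or d[:, :, 0].any() or d[:, :, -1].any()
    )
    if touches:
        warnings.warn(
            f"{margin_mm} mm expansion reaches the lattice boundary and is "
            "clipped; pad the grid to avoid truncating expanded volumes",
            stacklevel=3,
        )


def union_masks(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Voxelwise OR of pairwise-compatible masks (the combined candidate)."""
    if len(masks) == 0:
        raise ValueError("union of an empty list of masks")
    out = masks[0].data.copy()
    for m in masks[1:]:
        masks[0].require_compatible(m)
        out |= m.data
    return masks[0].with_data(out)


def min_coverage_margin(truth: BinaryMask, candidate: BinaryMask) -> float:
    """Smallest margin whose expansion of ``candidate`` contains ``truth``.

    Equals the maximum, over reference-tumor voxels, of the distance to
    the nearest candidate voxel (0 when the candidate already covers the
    truth).  Continuous mm value; rounding for presentation is left to the
    caller.
    """
    truth.require_compatible(candidate)
    if truth.is_empty() or candidate.is_empty():
        raise ValueError("minimum coverage margin undefined for empty masks")
    dist = _distance_to_mask(candidate)
    return float(dist[truth.data].max())


@dataclass(frozen=True)
class MarginReport:
    """Margin analysis for one (truth, candidate) pair."""

    candidate_name: str
    margins_mm: tuple[float, ...]
    expanded_volume_ml: tuple[float, ...]
    missed_volume_ml: tuple[float, ...]
    missed_percent: tuple[float, ...]
    min_coverage_margin_mm: float

    def to_dict(self) -> dict:
        return asdict(self)


def margin_report(
    truth: BinaryMask,
    candidate: BinaryMask,
    margins_mm: Sequence[float] = DEFAULT_MARGINS_MM,
    candidate_name: str = "candidate",
    allowed_region: BinaryMask | None = None,
) -> MarginReport:
    """Expanded volume and residual missed volume at each margin, plus the
    minimum margin ensuring complete coverage."""
    margins = tuple(float(m) for m in margins_mm)
    if any(b < a for a, b in zip(margins, margins[1:])):
        raise ValueError(f"margins must be sorted ascending, got {margins}")
    exp_ml, miss_ml, miss_pct = [], [], []
    for m in margins:
        grown = expand(candidate, m, allowed_region=allowed_region)
        exp_ml.append(mask_volume_ml(grown))
        ml, pct = missed_volume(truth, grown)
        miss_ml.append(ml)
        miss_pct.append(pct)
    return MarginReport(
        candidate_name=candidate_name,
        margins_mm=margins,
        expanded_volume_ml=tuple(exp_ml),
        missed_volume_ml=tuple(miss_ml),
        missed_percent=tuple(miss_pct),
        min_coverage_margin_mm=min_coverage_margin(truth, candidate),
    )
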