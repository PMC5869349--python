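"""Gradient-based radial PET lesion segmentation.

A reconstruction of the semiautomatic "gradient edge" class of PET
delineation tools: starting from a user-supplied seed inside the lesion,
intensity profiles are sampled along a quasi-uniform set of radii, the
tumor edge on each radius is placed at the steepest *falling* intensity
gradient (for a Gaussian-blurred step, the inflection point sits at the
true boundary regardless of contrast — the reason gradient placement
beats percentage-of-maximum thresholding), and the resulting per-direction
radius field is regularized for continuity of the edge over the direction
sphere before being rasterized into a binary VOI.

The commercial tool this emulates is proprietary and published only as a
one-sentence description; every constant here (direction count, profile
step, derivative-level threshold, continuity bound) is an explicit,
configurable parameter with phantom-validated defaults.  The segmenter is
fully deterministic and invariant to positive rescaling of the image
intensity (the derivative threshold is relative to the profile range).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import BinaryMask, ScalarImage

__all__ = [
    "PetEdgeParams",
    "RadialEdgeModel",
    "NoEdgeError",
    "icosphere_directions",
    "sample_ray",
    "edge_along_ray",
    "regularize_radii",
    "radii_to_mask",
    "petedge_segment",
]


class NoEdgeError(RuntimeError):
    """No falling intensity edge found (e.g. zero-contrast image)."""


# icosphere subdivision level -> vertex count
_ICOSPHERE_COUNTS = {0: 12, 1: 42, 2: 162, 3: 642, 4: 2562}


@dataclass(frozen=True)
class PetEdgeParams:
    """Tunable constants of the radial gradient segmenter.

    Attributes
    ----------
    n_directions
        Number of quasi-uniform ray directions (icosphere vertex counts:
        12, 42, 162, 642 or 2562).
    profile_step_mm
        Sampling step along each ray; ``None`` means half the smallest
        voxel spacing of the image.
    max_radius_mm
        Radial search limit.
    gradient_threshold per mm
        Minimum magnitude of the falling derivative, expressed as a
        fraction of the profile's global intensity range per millimetre;
        weaker edges are treated as absent.
    continuity_bound
        Maximum tolerated relative deviation of a radius from the median
        of its neighbouring directions before it is replaced.
    """

    n_directions: int = 642
    profile_step_mm: float | None = None
    max_radius_mm: float = 30.0
    gradient_threshold: float = 0.05
    continuity_bound: float = 0.5
    max_regularize_iter: int = 100
    converge_tol_mm: float = 0.01
    curvature_correction: bool = True


@dataclass(frozen=True)
class RadialEdgeModel:
    """Per-direction edge radii around a seed point.

    ``radii_mm`` entries are NaN where no edge was found on that ray
    (imputed during regularization).
    """

    seed_mm: tuple[float, float, float]
    directions: np.ndarray        # (n, 3) unit vectors
    radii_mm: np.ndarray          # (n,), NaN = missing
    neighbours: tuple[tuple[int, ...], ...]  # icosphere adjacency

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.radii_mm)


def icosphere_directions(n_directions: int = 642):
    """Quasi-uniform unit vectors + adjacency from an icosphere mesh."""
    for level, count in _ICOSPHERE_COUNTS.items():
        if count == n_directions:
            break
    else:
        raise ValueError(
            f"n_directions must be one of {sorted(_ICOSPHERE_COUNTS.values())}, "
            f"got {n_directions}"
        )
    mesh = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    dirs = np.asarray(mesh.vertices, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    nbrs: list[set[int]] = [set() for _ in range(len(dirs))]
    for i, j in mesh.edges_unique:
        nbrs[i].add(int(j))
        nbrs[j].add(int(i))
    return dirs, tuple(tuple(sorted(s)) for s in nbrs)


# ---------------------------------------------------------------------------
# Ray sampling and edge placement
# ---------------------------------------------------------------------------


def _world_to_index(image: ScalarImage, points_mm: np.ndarray) -> np.ndarray:
    return (points_mm - np.asarray(image.origin)) / np.asarray(image.spacing)


def sample_ray(
    image: ScalarImage,
    seed_mm: Sequence[float],
    direction: Sequence[float],
    step_mm: float,
    max_radius_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear intensity profile along ``seed + k*step*direction``.

    Returns ``(profile, outside)`` where ``outside`` flags samples beyond
    the lattice (they take the nearest boundary value).
    """
    if step_mm <= 0:
        raise ValueError("step must be positive")
    seed = np.asarray(seed_mm, dtype=float)
    seed_idx = _world_to_index(image, seed)
    if np.any(seed_idx < 0) or np.any(seed_idx > np.asarray(image.shape) - 1):
        raise ValueError(f"seed {tuple(seed)} mm lies outside the image")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    k = np.arange(int(np.floor(max_radius_mm / step_mm)) + 1)
    pts = seed[None, :] + k[:, None] * step_mm * d[None, :]
    idx = _world_to_index(image, pts)
    outside = np.any((idx < 0) | (idx > np.asarray(image.shape) - 1), axis=1)
    profile = ndimage.map_coordinates(
        image.data, idx.T, order=1, mode="nearest"
    )
    return profile, outside


def _edge_and_width(
    profile: np.ndarray, step_mm: float, gradient_threshold: float
) -> tuple[float | None, float | None]:
    """Edge radius and estimated blur SD along one ray.

    The blur SD is read off the curvature of the derivative peak: for a
    Gaussian-blurred step the derivative magnitude near its maximum is
    ``M exp(-(x-r*)^2 / (2 sigma^2))``, so the three-point second
    difference gives ``sigma^2 = M step^2 / (m0 - 2 m1 + m2)``.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 3:
        raise ValueError("profile too short for a centred derivative")
    rng = float(p.max() - p.min())
    # relative floor: interpolation round-off on a flat profile is not an edge
    if rng <= 1e-9 * float(np.abs(p).max()):
        return None, None
    # derivative at interior samples, intensity units per mm
    deriv = (p[2:] - p[:-2]) / (2.0 * step_mm)
    j = int(np.argmin(deriv))
    if -deriv[j] < gradient_threshold * rng:
        return None, None
    k = j + 1  # profile index of the steepest descent
    offset = 0.0
    sigma = None
    if 0 < j < deriv.size - 1:
        d0, d1, d2 = deriv[j - 1], deriv[j], deriv[j + 1]
        denom = d0 - 2.0 * d1 + d2
        if denom > 0:
            offset = float(np.clip(0.5 * (d0 - d2) / denom, -0.5, 0.5))
            sigma = float(np.sqrt(-d1 * step_mm**2 / denom))
    return (k + offset) * step_mm, sigma


def edge_along_ray(
    profile: np.ndarray,
    step_mm: float,
    gradient_threshold: float = 0.05,
) -> float | None:
    """Edge radius (mm) at the steepest falling gradient of the profile.

    Centred finite differences locate the most negative derivative; a
    parabolic fit through the three derivative samples around the optimum
    refines the position to sub-step accuracy.  Returns ``None`` when no
    falling edge exceeds ``gradient_threshold`` x (profile range) per mm
    (constant or monotone-increasing profiles have no edge).
    """
    radius, _ = _edge_and_width(profile, step_mm, gradient_threshold)
    return radius


# ---------------------------------------------------------------------------
# Continuity regularization
# ---------------------------------------------------------------------------


def regularize_radii(
    model: RadialEdgeModel,
    continuity_bound: float = 0.5,
    max_iter: int = 100,
    tol_mm: float = 0.01,
) -> RadialEdgeModel:
    """Enforce continuity of the edge over the direction sphere.

    Iteratively (a) imputes missing radii from the median of known
    neighbouring directions and (b) replaces radii deviating from their
    neighbour median by more than ``continuity_bound`` (relative) with
    that median, until the largest change falls below ``tol_mm`` or
    ``max_iter`` sweeps.  A uniform radius field is a fixed point.
    """
    radii = model.radii_mm.astype(float).copy()
    if np.all(np.isnan(radii)):
        raise NoEdgeError("no edge found in any direction")
    for _ in range(max_iter):
        new = radii.copy()
        for i, nbr in enumerate(model.neighbours):
            nbr_vals = radii[list(nbr)]
            nbr_vals = nbr_vals[~np.isnan(nbr_vals)]
            if nbr_vals.size == 0:
                continue
            med = float(np.median(nbr_vals))
            if np.isnan(radii[i]):
                new[i] = med
            elif med > 0 and abs(radii[i] - med) > continuity_bound * med:
                new[i] = med
        change = np.abs(np.where(np.isnan(radii), np.inf, new - radii))
        change[np.isnan(new)] = np.inf
        radii = new
        if not np.any(np.isnan(radii)) and np.nanmax(change) < tol_mm:
            break
    if np.any(np.isnan(radii)):  # isolated islands of missing directions
        known = ~np.isnan(radii)
        radii[~known] = float(np.median(radii[known]))
    return replace(model, radii_mm=radii)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def radii_to_mask(
    model: RadialEdgeModel,
    grid: BinaryMask | ScalarImage,
) -> BinaryMask:
    """Rasterize the closed radial edge surface onto a voxel grid.

    A voxel centre is inside when its distance to the seed does not
    exceed the edge radius interpolated (inverse-distance weighting of
    the 3 nearest direction nodes) at its direction.  Only the
    26-connected component containing the seed is kept.
    """
    radii = model.radii_mm
    if np.any(np.isnan(radii)):
        raise ValueError("model must be regularized before rasterization")
    if np.all(radii <= 0):
        raise ValueError("degenerate radius field (all radii 0)")
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    shape = np.asarray(grid.data.shape)
    seed = np.asarray(model.seed_mm, dtype=float)
    rmax = float(radii.max())

    # bounding box of the reachable region, in voxel indices
    lo = np.maximum(np.floor((seed - rmax - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((seed + rmax - origin) / spacing).astype(int) + 1, shape)
    out = np.zeros(tuple(shape), dtype=bool)
    if np.any(lo >= hi):
        raise ValueError("seed/radius region does not intersect the grid")

    axes = [origin[a] + np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    vec = np.stack([xx - seed[0], yy - seed[1], zz - seed[2]], axis=-1)
    dist = np.linalg.norm(vec, axis=-1)
    inside = np.zeros(dist.shape, dtype=bool)
    nz = dist > 0
    unit = vec[nz] / dist[nz][:, None]
    tree = cKDTree(model.directions)
    dd, ii = tree.query(unit, k=3)
    w = 1.0 / np.maximum(dd, 1e-12)
    r_interp = np.sum(w * radii[ii], axis=1) / np.sum(w, axis=1)
    inside[nz] = dist[nz] <= r_interp
    inside[~nz] = True  # the seed voxel itself
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside

    seed_idx = tuple(
        int(np.clip(round(v), 0, s - 1))
        for v, s in zip((seed - origin) / spacing, shape)
    )
    out[seed_idx] = True
    labels, _ = ndimage.label(out, structure=np.ones((3, 3, 3), dtype=bool))
    out = labels == labels[seed_idx]
    return BinaryMask(out, tuple(grid.spacing), tuple(grid.origin))


# ---------------------------------------------------------------------------
# Full segmenter
# ---------------------------------------------------------------------------


def petedge_segment(
    image: ScalarImage,
    seed_mm: Sequence[float],
    params: PetEdgeParams = PetEdgeParams(),
) -> BinaryMask:
    """Segment a lesion around ``seed_mm`` by radial gradient edge detection.

    Deterministic composition of ray sampling, per-ray edge placement,
    continuity regularization and rasterization.  Raises
    :class:`NoEdgeError` when no direction shows a falling edge (e.g. a
    zero-contrast image).
    """
    step = params.profile_step_mm
    if step is None:
        step = 0.5 * min(image.spacing)
    dirs, nbrs = icosphere_directions(params.n_directions)
    seed = np.asarray(seed_mm, dtype=float)

    # sample all rays in one interpolation call
    k = np.arange(int(np.floor(params.max_radius_mm / step)) + 1)
    pts = seed[None, None, :] + k[None, :, None] * step * dirs[:, None, :]
    idx = _world_to_index(image, pts.reshape(-1, 3))
    if np.any(idx[0] < 0) or np.any(idx[0] > np.asarray(image.shape) - 1):
        raise ValueError(f"seed {tuple(seed)} mm lies outside the image")
    profiles = ndimage.map_coordinates(
        image.data, idx.T, order=1, mode="nearest"
    ).reshape(len(dirs), len(k))

    radii = np.full(len(dirs), np.nan)
    for i in range(len(dirs)):
        r, sigma = _edge_and_width(profiles[i], step, params.gradient_threshold)
        if r is None or r <= 0:
            continue
        if params.curvature_correction and sigma is not None:
            # the gradient maximum of a blurred convex boundary sits
            # inward of the true edge by ~sigma^2/r; compensate, clamped
            # so a bad width estimate cannot run away
            r = r + min(sigma**2 / r, 0.25 * r)
        radii[i] = min(r, params.max_radius_mm)

    model = RadialEdgeModel(
        seed_mm=tuple(seed), directions=dirs, radii_mm=radii, neighbours=nbrs
    )
    model = regularize_radii(
        model,
        continuity_bound=params.continuity_bound,
        max_iter=params.max_regularize_iter,
        tol_mm=params.converge_tol_mm,
    )
    return radii_to_mask(model, image)
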