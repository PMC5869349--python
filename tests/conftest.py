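"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's EDT-based code paths:
surface distances are exhaustive O(n^2) pairwise scans, ball voxel counts
come from integer lattice enumeration, and exact Wilcoxon p-values come
from full sign-pattern enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from segmargin import BinaryMask


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------


def ball(shape, center, radius, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    """Digitized ball: voxel centres within radius (mm) of center (mm)."""
    ax = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    return BinaryMask(d2 <= radius**2, spacing, origin)


def ellipsoid(shape, center, semi_axes, spacing=(1.0, 1.0, 1.0)):
    ax = [np.arange(shape[a]) * spacing[a] for a in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    q = (
        ((xx - center[0]) / semi_axes[0]) ** 2
        + ((yy - center[1]) / semi_axes[1]) ** 2
        + ((zz - center[2]) / semi_axes[2]) ** 2
    )
    return BinaryMask(q <= 1.0, spacing)


def box(shape, lo, hi, spacing=(1.0, 1.0, 1.0)):
    """Axis-aligned solid block with true voxels in [lo, hi) per axis."""
    data = np.zeros(shape, dtype=bool)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return BinaryMask(data, spacing)


def random_mask(rng, shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0), p=0.2):
    """Random nonempty blob: thresholded smoothed noise keeps it clumpy."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.2)
    thr = np.quantile(field, 1.0 - p)
    data = field > thr
    if not data.any():
        data[tuple(rng.integers(0, s) for s in shape)] = True
    return BinaryMask(data, spacing)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_surface_points_mm(mask: BinaryMask) -> np.ndarray:
    """Surface voxel centres (mm) by explicit 6-neighbour scanning."""
    data = mask.data
    pts = []
    for idx in np.argwhere(data):
        x, y, z = idx
        on_surface = False
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            n = (x + d[0], y + d[1], z + d[2])
            if any(c < 0 or c >= s for c, s in zip(n, data.shape)) or not data[n]:
                on_surface = True
                break
        if on_surface:
            pts.append(idx)
    return np.asarray(pts, dtype=float) * np.asarray(mask.spacing)


def brute_directed_distances(a: BinaryMask, b: BinaryMask) -> np.ndarray:
    """Exhaustive closest-point distances from A-surface to B-surface."""
    pa = brute_surface_points_mm(a)
    pb = brute_surface_points_mm(b)
    diff = pa[:, None, :] - pb[None, :, :]
    return np.sqrt((diff**2).sum(-1)).min(axis=1)


def brute_hausdorff(a: BinaryMask, b: BinaryMask) -> float:
    return float(
        max(brute_directed_distances(a, b).max(), brute_directed_distances(b, a).max())
    )


def brute_mda(a: BinaryMask, b: BinaryMask) -> float:
    pooled = np.concatenate(
        [brute_directed_distances(a, b), brute_directed_distances(b, a)]
    )
    return float(pooled.mean())


def brute_min_coverage_margin(truth: BinaryMask, candidate: BinaryMask) -> float:
    """Max over truth voxels of the distance to the nearest candidate voxel."""
    pt = np.argwhere(truth.data).astype(float) * np.asarray(truth.spacing)
    pc = np.argwhere(candidate.data).astype(float) * np.asarray(candidate.spacing)
    diff = pt[:, None, :] - pc[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).min(axis=1).max())


def lattice_ball_count(radius: float, spacing=(1.0, 1.0, 1.0)) -> int:
    """Number of integer lattice points (scaled by spacing) within radius."""
    ns = [int(np.floor(radius / s)) for s in spacing]
    count = 0
    for i in range(-ns[0], ns[0] + 1):
        for j in range(-ns[1], ns[1] + 1):
            for k in range(-ns[2], ns[2] + 1):
                d2 = (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 + (k * spacing[2]) ** 2
                if d2 <= radius**2:
                    count += 1
    return count


def exact_signed_rank_p(differences) -> float:
    """Two-sided exact Wilcoxon signed-rank p by sign-pattern enumeration."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
    )
    cdf = np.mean(ws <= w_obs)
    sf = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(cdf, sf))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
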