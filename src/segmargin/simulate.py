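"""Synthetic tumor / reader-segmentation / PET phantom cohorts.

No patient data ship with this package; this module generates cohorts
with the statistical structure the margin analysis assumes, so that every
pipeline stage is exercisable end to end:

* **Ground-truth tumors** — star-convex irregular blobs: a base ellipsoid
  whose radius is modulated by band-limited random perturbations on the
  direction sphere, rescaled so the voxel-count volume matches a target
  drawn from a lognormal law (median 1.37 mL, truncated to the clinically
  observed 0.15–6.31 mL range of small significant prostate cancers).
* **Reader segmentations** — the candidate VOI a human reader would draw:
  the truth shrunk toward a random deep-interior anchor, decentred by a
  Gaussian spatial offset, with smooth boundary noise, calibrated by
  bisection on the shrink factor so the fraction of truth covered hits a
  configured target (defaults 0.21 / 0.20, i.e. ≈79–80 % of the tumor
  volume missed).  Reader error is deliberately decomposed into
  shrinkage + decentring + boundary noise, because required safety
  margins are driven by both undersegmentation and miscentring.
* **PET images** — piecewise-constant activity convolved with an
  isotropic Gaussian point-spread function (default FWHM 4.1 mm) plus
  Gaussian noise, the phantom input for the gradient segmenter.

Everything is reproducible from a single cohort seed (one seed sequence,
spawned per case, so adding cases never changes earlier ones).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, ScalarImage, SegmentationCase, mask_volume_ml, write_mask, write_image
from .petedge import (
    PetEdgeParams,
    RadialEdgeModel,
    icosphere_directions,
    petedge_segment,
    radii_to_mask,
)

__all__ = [
    "PetParams",
    "CohortConfig",
    "SimulatedCase",
    "simulate_truth",
    "simulate_reader",
    "simulate_pet",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class PetParams:
    """Phantom PET acquisition model."""

    background_suv: float = 1.0
    tumor_suv: float = 8.0
    psf_fwhm_mm: float = 4.1
    noise_sd_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.background_suv <= 0 or self.tumor_suv <= 0:
            raise ValueError("SUV levels must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Full generative configuration of a synthetic cohort.

    Defaults reproduce the study conditions the analysis is aimed at:
    small tumors (lognormal, median 1.37 mL, range 0.15–6.31 mL), two
    human readers covering ≈21 % / 20 % of the truth volume, 3 mm reader
    decentring SD, and PET resolution of 4.1 mm FWHM.
    """

    n_cases: int = 9
    grid_shape: tuple[int, int, int] = (72, 72, 72)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_volume_median_ml: float = 1.37
    tumor_volume_sigma: float = 1.0
    tumor_volume_range_ml: tuple[float, float] = (0.15, 6.31)
    irregularity: float = 0.3
    reader_coverage_targets: tuple[float, ...] = (0.21, 0.20)
    reader_offset_sd_mm: float = 3.0
    coverage_tolerance: float = 0.03
    pet_params: PetParams = field(default_factory=PetParams)
    petedge_params: PetEdgeParams = field(default_factory=PetEdgeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for c in self.reader_coverage_targets:
            if not (0 < c <= 1):
                raise ValueError(f"coverage target {c} outside (0, 1]")
        if self.reader_offset_sd_mm < 0 or self.irregularity < 0:
            raise ValueError("SDs and irregularity must be >= 0")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

_TRUTH_DIRECTIONS = 162  # icosphere nodes carrying the radius field


def _smooth_sphere_noise(
    rng: np.random.Generator, neighbours, n: int, passes: int = 2
) -> np.ndarray:
    """Band-limited zero-mean unit-SD random field on the direction sphere."""
    v = rng.standard_normal(n)
    for _ in range(passes):
        sm = v.copy()
        for i, nbr in enumerate(neighbours):
            sm[i] = 0.5 * v[i] + 0.5 * np.mean(v[list(nbr)])
        v = sm
    v -= v.mean()
    sd = v.std()
    return v / sd if sd > 0 else v


def _rasterize_radial(
    radii: np.ndarray,
    dirs: np.ndarray,
    center_mm: tuple[float, float, float],
    template: BinaryMask,
) -> BinaryMask:
    model = RadialEdgeModel(
        seed_mm=center_mm, directions=dirs, radii_mm=radii, neighbours=()
    )
    return radii_to_mask(model, template)


def draw_tumor_volume_ml(config: CohortConfig, rng: np.random.Generator) -> float:
    """Truncated-lognormal tumor volume draw (mL)."""
    lo, hi = config.tumor_volume_range_ml
    mu = np.log(config.tumor_volume_median_ml)
    for _ in range(1000):
        v = float(np.exp(rng.normal(mu, config.tumor_volume_sigma)))
        if lo <= v <= hi:
            return v
    raise RuntimeError("tumor volume law incompatible with the configured range")


def simulate_truth(
    config: CohortConfig,
    rng: np.random.Generator,
    target_volume_ml: float | None = None,
) -> BinaryMask:
    """Star-convex irregular ground-truth tumor centred in the grid.

    The base shape is a random ellipsoid (log-uniform axis anisotropy,
    volume-neutral); its radius field over ``162`` quasi-uniform
    directions is modulated by smooth random perturbations of relative
    amplitude ``config.irregularity`` and rescaled until the voxel-count
    volume matches the target within 2 %.
    """
    if target_volume_ml is None:
        target_volume_ml = draw_tumor_volume_ml(config, rng)
    target_mm3 = target_volume_ml * 1000.0
    shape = config.grid_shape
    spacing = config.spacing_mm
    template = BinaryMask(np.zeros(shape, dtype=bool), spacing)
    center = tuple(
        (shape[a] - 1) / 2.0 * spacing[a] for a in range(3)
    )

    dirs, nbrs = icosphere_directions(_TRUTH_DIRECTIONS)
    # volume-neutral ellipsoid anisotropy
    f = np.exp(rng.uniform(-0.35, 0.35, 3))
    f /= np.prod(f) ** (1.0 / 3.0)
    r0 = (3.0 * target_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    axes = r0 * f
    r_ell = 1.0 / np.sqrt(np.sum((dirs / axes) ** 2, axis=1))
    bump = _smooth_sphere_noise(rng, nbrs, len(dirs))
    radii = r_ell * np.clip(1.0 + config.irregularity * bump, 0.25, None)

    grid_capacity = min(
        (shape[a] - 1) / 2.0 * spacing[a] for a in range(3)
    )
    mask = None
    for _ in range(12):
        if radii.max() > grid_capacity:
            raise ValueError(
                f"target volume {target_volume_ml} mL needs radius "
                f"{radii.max():.1f} mm > grid capacity {grid_capacity:.1f} mm"
            )
        mask = _rasterize_radial(radii, dirs, center, template)
        vol = mask.count() * mask.voxel_volume_mm3
        if vol > 0 and abs(vol - target_mm3) / target_mm3 <= 0.02:
            break
        scale = (target_mm3 / max(vol, 1.0)) ** (1.0 / 3.0)
        radii = radii * scale
    return mask


# ---------------------------------------------------------------------------
# Reader emulation
# ---------------------------------------------------------------------------


def _reader_mask_at_scale(
    truth_f: np.ndarray,
    anchor_vox: np.ndarray,
    offset_vox: np.ndarray,
    scale: float,
    noise: np.ndarray,
    noise_amp: float,
    bbox: tuple,
) -> np.ndarray:
    """Shrunk, shifted, noise-perturbed copy of the truth (full-grid bool)."""
    (lo, hi) = bbox
    axes = [np.arange(lo[a], hi[a], dtype=float) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    coords = np.stack(
        [
            anchor_vox[a] + (g - anchor_vox[a] - offset_vox[a]) / scale
            for a, g in enumerate((xx, yy, zz))
        ]
    )
    vals = ndimage.map_coordinates(truth_f, coords, order=1, mode="constant", cval=0.0)
    vals = vals + noise_amp * noise[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    crop = vals > 0.5
    # a reader draws one connected VOI: drop disconnected noise specks,
    # keeping the component nearest the shrink anchor
    if crop.any():
        labels, n_comp = ndimage.label(crop, structure=np.ones((3, 3, 3), bool))
        if n_comp > 1:
            a = np.minimum(
                np.maximum(anchor_vox.astype(int) - lo, 0), np.asarray(crop.shape) - 1
            )
            keep = labels[tuple(a)]
            if keep == 0:
                counts = np.bincount(labels.ravel())
                counts[0] = 0
                keep = int(np.argmax(counts))
            crop = labels == keep
    out = np.zeros(truth_f.shape, dtype=bool)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = crop
    return out


def simulate_reader(
    truth: BinaryMask,
    coverage_target: float,
    offset_sd_mm: float,
    rng: np.random.Generator,
    tolerance: float = 0.03,
    noise_amp: float = 0.15,
) -> BinaryMask:
    """Emulated human-reader VOI covering ``coverage_target`` of the truth.

    The truth is shrunk about an anchor drawn near the deepest-interior
    point (the conspicuous lesion core both readers aim at), translated
    by a random-direction offset of half-normal magnitude (SD
    ``offset_sd_mm``) and perturbed by a smooth boundary-noise field;
    the shrink factor is then calibrated by bisection so that
    ``|seg ∩ truth| / |truth|`` is within ±``tolerance`` of the target.
    On very small truths (< 30 voxels) an exact match may be impossible;
    the closest achievable segmentation is returned.
    """
    if truth.is_empty():
        raise ValueError("truth mask is empty")
    if not (0 < coverage_target <= 1):
        raise ValueError(f"coverage target {coverage_target} outside (0, 1]")
    truth_f = truth.data.astype(np.float64)
    n_truth = truth.count()
    spacing = np.asarray(truth.spacing)

    # both readers aim at the conspicuous lesion core: anchor near the
    # deepest-interior point; decentring comes from the offset draw
    depth = ndimage.distance_transform_edt(truth.data, sampling=truth.spacing)
    core = np.argwhere(depth >= 0.9 * depth.max())
    anchor_vox = core[rng.integers(len(core))].astype(float)
    u = rng.standard_normal(3)
    u /= max(np.linalg.norm(u), 1e-12)
    offset_vox = u * abs(rng.normal(0.0, offset_sd_mm)) / spacing
    noise = ndimage.gaussian_filter(rng.standard_normal(truth.shape), sigma=2.0)
    nsd = noise.std()
    if nsd > 0:
        noise /= nsd

    tr_idx = np.argwhere(truth.data)
    pad = int(np.ceil(np.abs(offset_vox).max())) + 8
    lo = np.maximum(tr_idx.min(axis=0) - pad, 0)
    hi = np.minimum(tr_idx.max(axis=0) + pad + 1, np.asarray(truth.shape))
    bbox = (lo, hi)

    def coverage(scale: float) -> tuple[float, np.ndarray]:
        seg = _reader_mask_at_scale(
            truth_f, anchor_vox, offset_vox, scale, noise, noise_amp, bbox
        )
        return np.count_nonzero(seg & truth.data) / n_truth, seg

    # bisect toward the *smallest* shrink factor whose coverage reaches the
    # target: overshoot plateaus at coverage 1, so ties resolve downward
    s_lo, s_hi = 0.05, 1.6
    best_seg, best_err, best_s = None, np.inf, np.inf
    for it in range(30):
        # probe the identity scale first: a perfect reader (coverage 1,
        # no offset, no noise) then reproduces the truth exactly
        s = 1.0 if it == 0 else 0.5 * (s_lo + s_hi)
        cov, seg = coverage(s)
        err = abs(cov - coverage_target)
        if err < best_err - 1e-12 or (err <= best_err + 1e-12 and s < best_s):
            best_err, best_seg, best_s = err, seg, s
        if err == 0.0 or (err <= tolerance and cov < coverage_target):
            break
        if cov < coverage_target:
            s_lo = s
        else:
            s_hi = s
        if s_hi - s_lo < 1e-3 and best_err <= tolerance:
            break
    seg = best_seg
    if not seg.any():
        seg = seg.copy()
        seg[tuple(anchor_vox.astype(int))] = True
    return truth.with_data(seg)


# ---------------------------------------------------------------------------
# PET phantom
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def simulate_pet(
    truth: BinaryMask,
    pet_params: PetParams,
    rng: np.random.Generator | None = None,
) -> ScalarImage:
    """PET phantom: two-level activity map blurred by the scanner PSF.

    ``background_suv`` outside the tumor, ``tumor_suv`` inside, convolved
    with an isotropic Gaussian of FWHM ``psf_fwhm_mm``, plus independent
    Gaussian noise of SD ``noise_sd_fraction x tumor_suv``, clipped at 0.
    """
    act = np.where(
        truth.data, pet_params.tumor_suv, pet_params.background_suv
    ).astype(np.float64)
    if pet_params.psf_fwhm_mm > 0:
        sigma_vox = [
            pet_params.psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in truth.spacing
        ]
        act = ndimage.gaussian_filter(act, sigma=sigma_vox)
    if pet_params.noise_sd_fraction > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd_fraction > 0")
        act = act + rng.normal(
            0.0, pet_params.noise_sd_fraction * pet_params.tumor_suv, act.shape
        )
    return ScalarImage(np.clip(act, 0.0, None), truth.spacing, truth.origin)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCase:
    """One synthetic case: truth + readers + PET image + PET segmentation."""

    case: SegmentationCase
    pet: ScalarImage
    meta: dict = field(default_factory=dict)


def _centroid_mm(mask: BinaryMask) -> tuple[float, float, float]:
    com = ndimage.center_of_mass(mask.data)
    return tuple(
        mask.origin[a] + com[a] * mask.spacing[a] for a in range(3)
    )


def simulate_cohort(config: CohortConfig) -> list[SimulatedCase]:
    """Generate a fully reproducible synthetic cohort.

    Each case holds the ground-truth tumor, one reader segmentation per
    configured coverage target (``seg1``, ``seg2``, ...), a PET phantom,
    and ``seg3``: the gradient segmenter run on that phantom seeded at
    the truth centroid.  The per-case RNG streams are spawned from the
    cohort seed, so case *k* is identical regardless of ``n_cases``.
    """
    root = np.random.SeedSequence(config.seed)
    cases: list[SimulatedCase] = []
    for i, ss in enumerate(root.spawn(config.n_cases)):
        rng = np.random.default_rng(ss)
        target_ml = draw_tumor_volume_ml(config, rng)
        truth = simulate_truth(config, rng, target_volume_ml=target_ml)
        candidates: dict[str, BinaryMask] = {}
        meta: dict = {"target_volume_ml": target_ml,
                      "truth_volume_ml": mask_volume_ml(truth)}
        for r, cov in enumerate(config.reader_coverage_targets, start=1):
            seg = simulate_reader(
                truth,
                cov,
                config.reader_offset_sd_mm,
                rng,
                tolerance=config.coverage_tolerance,
            )
            candidates[f"seg{r}"] = seg
            meta[f"seg{r}_coverage"] = (
                np.count_nonzero(seg.data & truth.data) / truth.count()
            )
        pet = simulate_pet(truth, config.pet_params, rng)
        seg3 = petedge_segment(pet, _centroid_mm(truth), config.petedge_params)
        candidates[f"seg{len(config.reader_coverage_targets) + 1}"] = seg3
        cases.append(
            SimulatedCase(
                case=SegmentationCase(
                    case_id=f"case{i + 1:03d}", truth=truth, candidates=candidates
                ),
                pet=pet,
                meta=meta,
            )
        )
    return cases


def write_cohort(cases: list[SimulatedCase], out_dir: str | Path) -> None:
    """Write a cohort as NIfTI volumes plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sc in cases:
        d = out / sc.case.case_id
        d.mkdir(exist_ok=True)
        write_mask(sc.case.truth, d / "truth.nii.gz")
        for name, seg in sc.case.candidates.items():
            write_mask(seg, d / f"{name}.nii.gz")
        write_image(sc.pet, d / "pet.nii.gz")
        manifest.append({"case_id": sc.case.case_id, **sc.meta})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
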