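# Methods

This note records the models, conventions and numerical choices behind
`segmargin`, and what its synthetic validation does and does not show.

## Data model and geometry

All volumes live on a regular, axis-aligned, possibly anisotropic voxel
grid with axis order (x, y, z). World coordinates follow the
voxel-centre convention, `world = origin + index * spacing`; volumes are
`count x voxel volume / 1000` mL. Binary operations require identical
shape, spacing and origin — nothing is resampled implicitly (an explicit
nearest-neighbour resampler exists for deliberate regridding). Oblique
NIfTI affines are rejected rather than silently reduced: the analysis
assumes everything was registered to one axis-aligned grid beforehand.

## Similarity metrics

Dice and Jaccard are computed on voxel counts. Surfaces are voxel
centres whose 6-neighbourhood contains a false voxel (lattice-boundary
voxels included). Distances are centre-to-centre, spacing-aware, via
exact Euclidean distance transforms; HD is the full symmetric maximum
(no percentile variant) and MDA pools both directed closest-point sets
so every surface point of either mask carries equal weight (the
alternative — averaging the two directed means — weights the two
surfaces equally regardless of their point counts; pooling was chosen
and is asserted by the oracle tests). No sub-voxel surface
interpolation is attempted; the resulting bias is below half a voxel
diagonal and identical across HD, MDA and the margin machinery, which
deliberately share one distance geometry. Metrics on two empty masks
raise rather than return sentinels.

## Margins and coverage

Expansion by `m` mm thresholds the EDT of the mask complement, so
`expand` and `min_coverage_margin` are exact duals: the minimum coverage
margin is the maximum over truth voxels of the distance to the nearest
candidate voxel, returned as a continuous mm value (integer-looking
margins in reports are presentation rounding, not computation).
Expansions are clipped at the lattice and warn when they touch it; the
synthetic grids are sized so the largest margins analysed do not clip.
An optional allowed-region mask (e.g. an anatomical compartment)
truncates expansions by intersection; default unrestricted.

## Ellipsoid-formula estimates

Extents are measured along the lattice axes only (the canonical imaging
planes), with the full-voxel convention `(max − min + 1) × spacing` so a
single voxel has one-voxel extent. The formula constant 0.52
approximates π/6 ≈ 0.5236, so for digitized axis-aligned ellipsoids the
formula-to-count ratio tends to 0.993 as voxels shrink; for irregular,
non-convex VOIs the extents-based formula overestimates, which the
synthetic cohort reproduces.

## Radial gradient PET segmentation

The segmenter reconstructs the published behaviour of gradient-based
semiautomatic PET delineation tools; the commercial implementations are
proprietary, so every constant here is explicit and configurable:

* **Directions**: icosphere vertices (default 642); adjacency from mesh
  edges.
* **Profiles**: trilinear sampling along each ray (default step: half
  the smallest voxel spacing; search limit 30 mm); samples beyond the
  lattice take the boundary value and are flagged.
* **Edge placement**: most negative centred finite-difference
  derivative, refined by a parabolic fit to sub-step accuracy. Edges
  weaker than 5 %/mm of the profile's intensity range are treated as
  absent — the threshold is range-relative, making the segmenter
  invariant to positive intensity rescaling. For a Gaussian-blurred
  step, the inflection sits at the true boundary independent of
  contrast, which is why gradient placement is preferred over
  percentage-of-maximum thresholding.
* **Curvature correction**: for a *convex* blurred boundary the radial
  gradient maximum sits inward of the true edge by ≈ σ²/R. The blur SD
  σ is estimated per ray from the width of the derivative peak (the
  three-point second difference of a Gaussian-shaped peak gives
  σ² = M·step²/Δ²m), and the edge radius is corrected by +σ̂²/r, clamped
  at 0.25 r so a poor width estimate cannot run away. Without this
  correction the volume of a 6 mm-radius sphere at 4.1 mm FWHM is
  underestimated by ~24 %; with it, phantom volume errors stay within
  ~6 % across radii 6–15 mm and contrasts 4:1–20:1.
* **Continuity regularization**: missing radii are imputed from the
  median of neighbouring directions, and radii deviating from their
  neighbour median by more than 50 % are replaced by it, iterated to a
  fixed point (max 100 sweeps, 0.01 mm tolerance). Diffusion-style
  smoothing iterated to convergence was rejected: it flattens a
  legitimate ellipsoidal radius field toward a constant, trading real
  anisotropy for smoothness.
* **Rasterization**: inverse-distance interpolation of the three
  nearest direction nodes gives a radius for every voxel direction;
  the 26-connected component containing the seed is kept.

The segmenter is deterministic; the seed coordinate replaces the
interactive click of the clinical workflow.

## Shape-based interslice interpolation

Sparse contour stacks (3 mm apart, as in whole-mount sectioning
protocols) are rebuilt by converting each slice to a capped signed
Euclidean distance field (negative inside), interpolating the fields
linearly along z and taking the sub-zero level set. Knot slices are
reproduced bit-exactly. The cap (default one slice gap) encodes the
assumption that a structure absent from a section ends within one gap of
its last outline; it governs how fast lesion poles taper toward an empty
neighbouring slice. A nearest-slab replication mode exists for
comparison.

Known limitation: the z-extent of a lesion pole beyond its last
non-empty contour is unobservable from the stack, so small lesions lose
polar volume. Measured on digitized spheres re-sampled at 3 mm and
reconstructed at 1 mm, the volume deficit averaged over the phase of the
sectioning grid is ≈ 2 % at 20 mm diameter, ≈ 3.5 % at 16 mm, but ≈ 8 %
(range 4–19 %, alignment-dependent) at 12 mm — at four gaps per diameter
the missing cap information dominates, and no variant evaluated
(field-cap tuning, full-3D EDT interpolation) removes it. Volumes of
lesions spanning ≲ 4 gaps should be treated as lower bounds.

## Synthetic cohort generator

The generator reproduces the statistical situation the analysis is
designed for; it is a simulation of segmentation *behaviour*, not of
image appearance.

* **Truth tumors**: star-convex blobs — a random ellipsoid (volume-
  neutral log-uniform axis anisotropy in ±0.35) whose radius field over
  162 icosphere directions is modulated by smoothed Gaussian
  perturbations of relative amplitude 0.3, rescaled until the voxel
  volume matches the target within 2 %. Volumes follow a lognormal law
  with median 1.37 mL and log-SD 1.0, truncated to 0.15–6.3 mL — the
  volume range of small, clinically significant prostate tumors; the
  distributional form is a modelling choice (only median and range are
  constrained). Single connected lesions only; multifocality is out of
  scope.
* **Reader segmentations**: the truth shrunk about an anchor drawn near
  its deepest-interior point (readers aim at the conspicuous core),
  displaced in a uniformly random direction by |N(0, 3 mm)|, perturbed
  by a smooth boundary-noise field (amplitude 0.15 of the indicator),
  restricted to one connected component, and calibrated by bisection on
  the shrink factor until the covered fraction of the truth is within
  ±0.03 of the target (defaults 0.21 and 0.20, i.e. ~79/80 % missed).
  Decomposing reader error into shrinkage + decentring + boundary noise
  is what makes required margins exceed pure erosion depth. Under these
  defaults two independent readers agree at Dice ≈ 0.35 on average
  (bracket 0.25–0.55 over large cohorts), matching the low inter-reader
  agreement regime of interest. On truths under ~30 voxels the coverage
  target may be unreachable; the closest achievable segmentation is
  returned.
* **PET phantoms**: two-level activity (background 1, tumor 8 by
  default) convolved with an isotropic Gaussian PSF of 4.1 mm FWHM plus
  Gaussian noise (SD = 5 % of tumor level), clipped at zero. No
  sinogram/reconstruction physics, no partial-volume correction.
* **Reproducibility**: one seed sequence per cohort, spawned per case,
  so case *k* is identical whatever the cohort size.

What passing synthetic tests shows: the metrics, margin geometry and
statistics are correct, and the qualitative cohort findings (union
candidates dominate; decentred under-segmentation forces margins well
beyond the erosion depth) emerge from the generative structure. What it
does not show: anything about real image contrast, registration error,
or reader psychology — the generator's coverage targets are inputs, not
discoveries.

## Cohort pipeline and statistics

Per case, every candidate (plus the union `seg4` of all non-empty
candidates) gets a similarity report, a margin report and an
ellipsoid-formula estimate (no estimate for the union, which is not a
drawn VOI). Empty candidates are recorded as excluded and contribute to
no summary for that candidate. Summaries report mean, SD, median,
min–max per metric per candidate. Wilcoxon signed-rank (paired) uses the
exact null for n ≤ 20 without tied or zero differences, otherwise the
normal approximation with tie correction; zero differences are dropped
(Wilcoxon's original rule), and an all-zero comparison reports p = 1
with a flag. The unpaired comparison is the Mann–Whitney U test under
the same exact/asymptotic switch. No multiple-testing correction is
applied by default (raw two-sided p at α = 0.05); the comparisons run
per cohort are few and pre-specified.

## Problem sizes

Default synthetic grids are 72³ voxels at 1 mm isotropic — large enough
that 6.3 mL tumors plus 15 mm expansions never clip. The validation
suite uses 12³ grids where it checks against O(n²) brute-force oracles,
phantom grids of ~40–60³ for the PET segmenter, and cohorts of 9–200
cases for calibration checks; `scripts/acceptance.py` uses 60 cases.
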