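# segmargin

Segmentation-accuracy and safety-margin analysis for focal tumor therapy
planning.

Focal therapies (ablation, focal radiotherapy) treat only the visible
lesion plus a safety margin, so everything hinges on how much tumor the
pre-treatment segmentation actually misses. Studies that register
whole-mount histology to in-vivo imaging consistently find that reader-
and PET-derived target volumes cover only a minority of the true tumor.
`segmargin` packages the quantitative machinery of such studies: given a
reference-standard ("truth") tumor VOI and one or more candidate
segmentations on a common voxel grid, it computes how well each candidate
agrees with the truth, how much tumor each misses under millimetre safety
margins, and the smallest margin that guarantees complete coverage.

It is written for imaging scientists validating segmentation protocols,
and runs entirely on synthetic cohorts when no patient data are at hand.

## What it computes

For truth volume $B$ and candidate $A$ (binary VOIs on one grid):

* **Overlap**: Dice $= 2|A\cap B|/(|A|+|B|)$ and Jaccard
  $=|A\cap B|/|A\cup B|$.
* **Surface distances** (voxel-centre surfaces, anisotropic-spacing-aware
  Euclidean distance transforms): Hausdorff distance
  $\mathrm{HD} = \max$ over all surface points of the distance to the
  closest point of the other surface, and the mean distance to agreement
  $\mathrm{MDA}$ (mean of the pooled closest-point distances).
* **Missed (underestimated) tumor volume**: $|B \setminus A|$ in mL and
  as % of $|B|$.
* **Safety margins**: isotropic expansion of $A$ by $m$ mm (EDT
  thresholding), residual missed volume at each margin (default 5 and
  10 mm), and the **minimum coverage margin**
  $\min\{m : B \subseteq A \oplus m\} = \max_{x \in B} d(x, A)$.
* **Union candidates**: the voxelwise union of all available
  segmentations of a tumor, which by set algebra misses no more than its
  best part — the mechanism that makes combining independent
  segmentations effective.
* **Ellipsoid-formula volume estimates** from the maximal extents in the
  three canonical planes, $V = L \times W \times H \times 0.52$.
* **Wilcoxon comparisons** across a cohort (paired signed-rank, unpaired
  rank-sum; exact null for small samples without ties).

Two more components make the analysis self-contained:

* a **radial gradient PET segmenter**: intensity profiles along
  quasi-uniform rays from a seed, edge placement at the steepest falling
  gradient (with a curvature correction for convex blurred boundaries),
  continuity regularization of the radius field over the direction
  sphere, and rasterization to a VOI;
* **shape-based interslice interpolation** to rebuild a continuous 3D
  mask from contour slices spaced 3 mm apart, as when whole-mount
  histology is stacked into a reference volume;
* a **synthetic cohort generator**: irregular star-convex tumors with a
  lognormal volume law (median 1.37 mL), reader-like under-segmentations
  calibrated to cover a configurable fraction of the truth (defaults
  0.21/0.20), and PET phantoms blurred with a 4.1 mm FWHM point-spread
  function.

## Worked example

```python
import segmargin as sm

config = sm.CohortConfig(n_cases=9, seed=42)
cases = sm.simulate_cohort(config)
result = sm.analyze_cohort([sc.case for sc in cases], margins_mm=(5.0, 10.0))

for cand in ("seg1", "seg2", "seg3", "seg4"):
    missed = result.candidate_values(cand, "missed_percent")
    margin = result.candidate_values(cand, "min_coverage_margin_mm")
    print(f"{cand}: missed {missed.mean():5.1f} % of the tumor volume, "
          f"margin to cover every tumor {margin.max():4.1f} mm")

test = sm.compare_candidates(result, "missed_volume_ml", ("seg4", "seg1"))
print(f"union vs reader 1, paired Wilcoxon on missed volume: "
      f"W+ = {test['statistic']:.0f}, p = {test['p_value']:.4f}")
```

prints

```
seg1: missed  80.4 % of the tumor volume, margin to cover every tumor 10.2 mm
seg2: missed  80.1 % of the tumor volume, margin to cover every tumor 10.8 mm
seg3: missed  23.5 % of the tumor volume, margin to cover every tumor  2.8 mm
seg4: missed  20.5 % of the tumor volume, margin to cover every tumor  2.8 mm
union vs reader 1, paired Wilcoxon on missed volume: W+ = 0, p = 0.0039
```

`seg1`/`seg2` are the simulated human readers (calibrated to cover ~21 %
and ~20 % of each tumor), `seg3` is the gradient segmenter run on the
simulated PET, and `seg4` is their union. The readers miss ~80 % of the
tumor and would need ~10 mm margins to cover every lesion in this small
cohort; the union candidate misses the least and needs the smallest
margin — exactly the structural behaviour the margin analysis is built to
quantify. `W+ = 0` means the union never missed *more* than reader 1 in
any case.

The same workflow is available from the shell:

```bash
segmargin simulate --n-cases 9 --seed 42 --out cohort/
segmargin analyze --cohort cohort/ --margins 5,10 --out results/
segmargin petedge --image cohort/case001/pet.nii.gz --seed 35.5,35.5,35.5 --out seg3.nii.gz
```

`analyze` writes `table_accuracy.csv` (per-candidate agreement with
truth), `table_agreement.csv` (pairwise inter-candidate agreement),
`table_margins.csv` (margin analysis) and `tests.json`.

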