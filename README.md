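# aneumorph

Quantifies the 3D morphology of vascular (aneurysm-like) segmentations and
compares women vs men with a transformation / multiple-imputation /
regression pipeline — exercised entirely on synthetic voxel phantoms and
simulated cohorts with known ground truth.

## What it does

- **meshing** — binary masks (NIfTI or arrays + spacing) are resampled to a
  harmonized voxel size, reduced to the largest 26-connected component, and
  converted to watertight triangle meshes with marching cubes (Gaussian
  field pre-smoothing for sub-voxel accuracy). Mesh integrals give volume
  (divergence theorem) and surface area.
- **morphometry** — IBSI shape features (sphericity `(36πV²)^⅓ / A`,
  elongation and flatness from voxel-cloud PCA eigenvalues) plus local
  descriptors: per-vertex principal curvatures by quadric fitting in the
  vertex tangent frame, Koenderink shape index
  `(2/π)·atan((κ1+κ2)/(κ1−κ2))` and curvedness `√((κ1²+κ2²)/2)`,
  aggregated by the median over valid vertices. Display copies ×100.
- **phantoms** — spheres, ellipsoids, capsules and bleb-decorated spheres
  voxelized with closed-form truth records (independent oracles).
- **cohort** — cohort simulator with configurable sex effects on each
  morphology parameter, realistic covariate marginals, MCAR/MAR missingness
  in smoking, index-aneurysm selection and exclusion flow accounting.
- **stats** — log / Box-Cox transforms, Z-standardization, median
  dichotomization, linear and logistic women-vs-men contrasts, chained
  multiple imputation of smoking, Rubin's-rules pooling (Barnard–Rubin df),
  and the noncentral-F sample-size calculation.
- **pipeline** — orchestrates cohort → transforms → imputation → pooled
  univariable/multivariable results, two sensitivity analyses
  (drop-smoking; complete-case), rupture-prone direction annotation, and a
  morphometry batch runner.

## CLI

```bash
aneumorph phantoms make --kind sphere --radius 10 --spacing 0.5 --out sphere.nii
aneumorph morph run --mask-dir masks/ --out features.csv
aneumorph cohort simulate --n 326 --seed 1 --out cohort.csv
aneumorph analyze run --cohort-csv cohort.csv --out-dir results/
aneumorph analyze sensitivity --cohort-csv cohort.csv --out-dir results/
aneumorph power --predictors 8 --f2 0.05
```

Analysis options (adjustment set, imputation m/iterations, morphometry
spacing/smoothing) can be supplied via a YAML config (`--config`, keys
`analysis:` and `morphometry:`).

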