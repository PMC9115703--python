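# owhshapes

Microglial morphology quantification for organotypic whole-hemisphere
(OWH) brain-slice studies of hypoxic-ischemic injury.

Microglia change shape when the brain is injured: ramified surveilling
cells retract their processes and become compact and ameboid, or —
in some regions — hypertrophy into hyper-ramified forms. In OWH slice
models of oxygen–glucose deprivation (OGD), these regional shifts in
morphology carry information about how severely a region was injured and
whether a candidate treatment (e.g., erythropoietin or acetoacetate)
protected it. `owhshapes` implements the full analysis pipeline:

- **segmentation** of marker-channel fluorescence images: Otsu threshold,
  removal of objects under 25 pixels, hole filling, sub-pixel outlines;
- **morphometrics** per cell: perimeter *P*, area coverage *A* (pixels
  inside the outline), circularity 4π*A*/*P*² (1 for a disc, → 0 for
  filamentous shapes), and whole-study cell counts as 5 × the 20%
  test-split counts;
- **shape modes**: outlines resampled to *N* = 50 arc-length registration
  coordinates, normalized, Procrustes-aligned (rotation + cyclic shift,
  no reflections), embedded by PCA, and clustered by k-means into *k* = 5
  shape modes (SMs);
- **regional statistics**: Kruskal–Wallis + Dunn comparisons on a-priori
  pairs; neuroprotection measured against the regional OGD 2 h median of
  percent PI-positive cells (protected ⇔ PI% strictly below it); and
  logistic models predicting regional neuroprotection from SM proportion
  shifts, reporting the odds ratio per percentage point with Wald 95% CI
  and in-sample AUROC;
- a **synthetic-data generator** producing two-channel images and
  regional outcome tables with known ground truth (phenotype mixtures per
  region × group × sex, and a tunable coupling between phenotype shifts
  and protection), so every stage is testable end to end.

It is intended for researchers analyzing slice-culture or histology
images who want a reproducible, scriptable alternative to GUI workflows.

## Worked example

Render a synthetic cortex image after 2 h OGD, segment it, and measure
every cell:

```python
import numpy as np
from owhshapes import StudyDesign, render_image, segment_image, measure_cells
from owhshapes.image_prep import MARKER

design = StudyDesign(seed=0)
rng = np.random.default_rng(0)
image, truth = render_image(design, "cortex", "OGD2h", "F", 20, rng, image_id="demo")
mask, cells = segment_image(image.channel(MARKER), image_id="demo")
morph = measure_cells(cells)
print(f"threshold {mask.threshold_used:.0f}, {len(cells)} cells ({len(truth)} rendered)")
print(morph[["perimeter", "area_coverage", "circularity"]].describe().loc[["mean", "50%"]].round(3))
```

```
threshold 3785, 20 cells (20 rendered)
      perimeter  area_coverage  circularity
mean    222.192         489.95        0.400
50%     249.673         452.50        0.095
```

All 20 rendered cells are recovered; the low median circularity (0.095)
reflects the branched phenotypes dominating the injured-cortex mixture.

Simulate a study (6 regions × 8 slices/group) and ask whether the
region's injury-induced shift toward the ameboid phenotype predicts
protection by treatment:

```python
from owhshapes import (StudyDesign, simulate_regional_outcomes, sm_shift,
                       dichotomize_protection, predict_protection_from_sm_shift)

design = StudyDesign(groups=("NC", "OGD2h", "Epo"), slices_per_cell_of_design=4, seed=0)
table = simulate_regional_outcomes(design)
phen = list(design.phenotypes)
for p in phen:
    table[f"p_{p}"] = table[f"n_{p}"] / design.cells_per_image
props = table.groupby(["region", "group"], as_index=False)[[f"p_{p}" for p in phen]].mean()
shifts = sm_shift(props, "OGD2h", "NC", proportion_cols=[f"p_{p}" for p in phen])
protection = dichotomize_protection(table, treatment_groups=("Epo",))
results, roc = predict_protection_from_sm_shift(shifts, protection, predictors=["d_p_ameboid"])
print(results[["model", "OR", "ci_low", "ci_high", "auroc"]].round(3).to_string(index=False))
```

```
      model    OR  ci_low  ci_high  auroc
d_p_ameboid 1.186   1.028    1.369  0.821
```

Each percentage-point increase in a region's ameboid proportion after
injury multiplies the odds that a treated slice in that region is
protected by 1.19 (95% CI 1.03–1.37), and the shift alone discriminates
protected from unprotected region-slices with AUROC 0.82.

The full pipeline (synthesis → channel/quadrant prep → stratified split →
segmentation → morphometrics → shape modes → statistics) runs from one
config with a provenance manifest:

```bash
owhshapes run --out results/run1 --seed 7
```

or from Python via `owhshapes.run_pipeline(config, out_dir)`. Subcommands
(`generate`, `split`, `segment`, `fit`, `assign`, `stats`) expose each
stage over files.

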