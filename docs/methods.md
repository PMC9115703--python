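# Methods

## Overview

`owhshapes` quantifies microglial morphology in organotypic whole-hemisphere
(OWH) brain-slice fluorescence images and relates regional shifts in
morphological phenotype to treatment response after oxygen–glucose
deprivation (OGD). The chain is:

1. **Image preparation** — split two-channel frames (microglial marker +
   nuclear stain) by channel, tile each frame into four quadrants to
   increase image count, and divide images 80:20 into train/test sets
   stratified by (sex, region, treatment group).
2. **Segmentation** — Otsu threshold on the marker channel, removal of
   objects smaller than 25 pixels, hole filling, connected-component
   labeling, and sub-pixel outline extraction.
3. **Morphometrics** — perimeter, area coverage and circularity per cell;
   whole-study cell counts estimated as 5 × the test-split counts.
4. **Shape modes** — each outline is resampled to N = 50 arc-length
   registration coordinates, normalized, Procrustes-aligned, embedded by
   PCA, and clustered by k-means into k = 5 shape modes (SMs); test cells
   are assigned to the nearest trained mode.
5. **Regional statistics** — Kruskal–Wallis/Dunn group comparisons on
   a-priori pairs, a neuroprotection metric based on propidium-iodide (PI)
   positive percentages, and logistic models predicting regional
   neuroprotection from per-region SM proportion shifts (odds ratios, Wald
   95% CIs, in-sample AUROC).

A synthetic-data module generates both the images and the regional outcome
tables with known ground truth, so every stage is testable without
restricted microscopy data.

## Segmentation conventions

Numerical conventions are fixed so that results are bit-reproducible:

- The Otsu threshold maximizes between-class variance over the observed
  intensity histogram; ties break toward the smallest threshold, and
  foreground is strictly `> t`. Applied per processed image (i.e., per
  quadrant).
- Size filtering removes components with **fewer than** 25 pixels (a 25-px
  object is kept), judged before hole filling; filling then closes
  background regions not connected to the image border. A flag reverses
  the order for sensitivity analysis.
- Foreground components use 8-connectivity, holes 4-connectivity — the
  complementary pairing that avoids topological paradoxes.
- Border-touching cells are kept and flagged (an option excludes them).

Outlines are traced at the 0.5 iso-level of the hole-filled component mask
(marching squares), then smoothed with a 5-point closed moving average.
The raw marching-squares polygon is a staircase whose length overestimates
smooth boundaries by roughly 5% (measured on a digital disc of radius 50);
after smoothing the disc perimeter is within 0.1% of 2πr and within 2% for
radii ≥ 10, while the enclosed area changes by under 1% for objects above
the size filter. Orientation is normalized to a positive shoelace sum in
(row, col) coordinates.

## Morphometrics

- `perimeter`: Euclidean length of the closed outline polygon.
- `area_coverage`: raw pixel count inside the outline (holes filled) — the
  quantity used for counting and reporting.
- `circularity = 4πA/P²` with `A` the **shoelace area of the outline
  polygon**, clipped to ≤ 1. Using the polygon area rather than the pixel
  count keeps the ratio ≤ 1 for small discs, where a pixel-count area
  paired with a sub-pixel perimeter can exceed 1. A disc scores ~1;
  branched cells score near 0.

Total cells per region/slice are estimated as 5 × the test-split count
(the test fraction is 0.20); a contamination guard rejects counts that
include training images.

## Shape-mode model

- **Registration**: 50 points equally spaced by arc length from the
  outline's first vertex, preserving traversal direction. Normalization
  subtracts the centroid and divides by the root-mean-square point radius.
- **Alignment**: generalized Procrustes. For each shape the cyclic
  start-index ambiguity is removed by exhaustive search over all 50
  shifts (via FFT cross-correlation), with the optimal rotation in closed
  form per shift; the mean is re-estimated and renormalized until it moves
  less than 1e-8 RMS or 100 iterations. Reflections are never applied:
  the chirality of ramification patterns is biologically meaningful.
- **PCA**: eigendecomposition of the flattened 100-dimensional
  coordinates; the smallest leading basis explaining ≥ 95% of variance is
  retained (configurable). The retention rule is a package choice — only
  N = 50 and k = 5 are fixed by the protocol.
- **k-means**: 20 greedy-seeded restarts, squared-Euclidean inertia,
  fixed seed. Cluster labels map to SM indices 1..k by descending cluster
  size (ties by centroid norm) so numbering is reproducible; the
  underlying SM numbering is otherwise arbitrary.
- **Assignment**: registration against the trained mean (rotation +
  cyclic shift only), projection on the retained basis, nearest centroid;
  ties go to the lowest SM index. Degenerate outlines are counted as
  unassignable rather than failing a run.

Assignments are invariant to translation, scaling and rotation of the
input outline (verified to 1e-6 in the registered coordinates).

## Regional statistics

- **Group comparisons**: Kruskal–Wallis H with tie correction; Dunn z
  tests restricted to the a-priori pairs (injury vs control, injury vs
  each treatment); Holm adjustment over those pairs only (configurable).
- **Neuroprotection**: for a treated slice,
  `100 × (ref − PI%) / ref` where `ref` is the median PI% of the
  OGD 2 h slices in the same region; the binary outcome is
  `protected ⇔ PI% < ref` with strict inequality (a tie is not
  protection).
- **Morphology-change regressions**: identity-link linear model of
  per-slice neuroprotection % on the region-level change of a morphology
  parameter; R² and slope p reported.
- **SM odds contrasts**: per mode, a cell-level logistic model (that mode
  vs all others) with sex + region×group terms; references are female,
  cortex, and OGD 2 h. Contrasts: sex (M vs F), each region vs cortex,
  and each treatment vs OGD 2 h within region, as Wald ORs with 95% CIs.
  Cells are treated as independent; empty design cells yield rows flagged
  `inestimable` instead of exceptions.
- **Protection prediction**: per-SM logistic models of the protected
  indicator on the region's SM proportion shift (OGD 2 h vs control, in
  percentage points), plus one combined multi-SM model. Reported: OR per
  percentage point, Wald 95% CI, in-sample AUROC computed by the rank
  (Mann–Whitney) statistic with ties counted ½. In-sample AUROC matches
  how such slice studies are usually summarized; no cross-validation by
  default. Perfectly separating predictors are reported with AUROC 1.0
  and a `separation` flag; a single-class outcome raises.

### Known inferential limitation

All treated slices of a region are dichotomized against the *same*
empirical 8-slice reference median, which induces intraclass correlation
(~0.16 at the default design) that the independence-based Wald variance
ignores. Under a null coupling the 95% CI consequently contains 1 in
about 88% of replicates rather than 95%. A region-clustered robust
variance with t(G−1) critical values (`cluster_by_region=True`) brings the
null containment toward nominal but is very conservative with only six
regions and roughly halves power in coupled designs, so the conventional
independence-based Wald CI remains the default. Consumers should read the
single-SM CIs as mildly anti-conservative at protocol-scale designs.

## Synthetic data

The generator emulates the two data streams the analysis needs.

**Images.** Cells of three archetypes are stamped onto a noisy 16-bit
background without overlap (rejection sampling, bounded retries; cells lie
fully inside the frame so segmentation edge-handling can be tested
separately):

| archetype | area (px, mean ± sd) | branches | branch length | typical circularity |
|---|---|---|---|---|
| ameboid | 220 ± 30 | 0 | — | ≥ 0.85 |
| ramified | 420 ± 60 | 5 | 28 px | < 0.2 |
| hyper-ramified | 700 ± 90 | 9 | 30 px | < 0.1 |

Sizes sit well above the 25-pixel filter by design. The nuclear channel
carries one small disc per cell for format fidelity; segmentation uses the
marker channel only. Rendered stamps are hole-free, matching the
hole-filled masks segmentation produces. One pseudo-random stream per
study is seeded from the config; per-image sub-streams derive by stable
hashing of image metadata, so adding images does not perturb existing
ones. Identical (design, seed) reproduce byte-identical output.

**Regional outcomes.** PI% per (region, group, sex, slice) follows
`baseline(region) + injury(region) × g × (1 − f) + noise`, with g = 0 for
control, ½ for OGD 1 h, 1 otherwise, Gaussian slice noise (sd 10
percentage points), and clipping to [0, 100]. For treatment groups the
protected fraction is `f = 2σ(Σ_k β_k Δp_k) − 1`, where Δp_k is the
region's true injury-induced shift of phenotype k in percentage points and
β the per-phenotype coupling (defaults: ameboid +0.08, hyper-ramified
−0.03, ramified 0). Zero coupling gives f = 0 — a null design; the
defaults place the study in the regime where a one-point increase in the
coupled phenotype's proportion raises the odds of protection by ~1.2×,
with single-predictor AUROC near 0.8 at six regions × eight slices/group.
Default regional injury shifts move mixture mass toward ameboid in grey
matter (cortex +20 points … hippocampus +8) and toward hyper-ramified in
thalamus (−4) and white matter (−8), mirroring deramification of grey
matter and hypertrophy of white-matter microglia after injury.

PI outcomes are simulated at the (region, slice) level — the analysis
consumes only percentages — and the tabular simulator
(`simulate_regional_outcomes`) runs without rendering pixels, which is how
the 200-replicate parameter-recovery experiments stay cheap; there the
true per-cell phenotype labels stand in for shape-mode labels.

**What the generator does not emulate**: point-spread blur, z-stacks,
illumination gradients, touching/overlapping cells, staining variability,
or uncertainty in manual PI counting. Passing tests therefore demonstrate
correctness of the algorithms and calibration of the statistics under the
stated model, not robustness to those real-data artifacts.

## Split and tiling conventions

- Quadrants use floor-division boundaries: row `H//2` starts the bottom
  pair, column `W//2` the right pair, so larger remainders go
  rightward/downward; the four tiles partition the pixels exactly. A cell
  straddling a tile boundary appears as one object per tile — a documented
  consequence of disjoint tiling.
- The stratified split sends `round(0.2 n)` images per stratum to test,
  raised so the **test** side keeps at least 2 images (the side whose
  counts the ×5 scaling treats as representative); a flag enforces the
  floor on train instead. The draw is a deterministic function of the
  sorted image ids and the seed, hence input-order invariant. Strata with
  fewer than 3 images are rejected up front.

## Problem sizes used in tests and the acceptance script

Simulation sizes are chosen to estimate each property tightly while
keeping the default runs quick on one core: 100 images for the Otsu
oracle, 600 outlines (3 × 200) for cluster recovery, 2,000 Kruskal–Wallis
null simulations, 500 coverage replicates at n = 500, 200 study replicates
per arm of the parameter-recovery experiment, and a 108-image study
(3 regions × 3 groups × 2 sexes × 2 slices) for the end-to-end image
pipeline summary.
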