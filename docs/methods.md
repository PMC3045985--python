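# Methods

`mmhisto` classifies prostate tissue samples as cancerous or benign from two
co-registered modalities: a standard H&E-stained brightfield image
(~0.9636 µm/pixel) and a cell-type label raster derived upstream from
infrared (FT-IR) spectroscopic imaging (~6.25 µm/pixel; labels background /
epithelium / stroma / other). The IR map supplies what the stain cannot:
a reliable delineation of the epithelium, the compartment whose architecture
is diagnostic. The pipeline is: registration → lumen and nucleus
segmentation → 67 morphological features → two-stage feature selection →
cost-balanced RBF-SVM with cross-validated ROC/AUC evaluation.

## Registration

Both images are reduced to binary tissue masks (H&E: a pixel is tissue
unless *all three* channels exceed 200; IR: label ≠ background). The
spatial model is a similarity transform — translation `(tx, ty)`, rotation
`θ`, isotropic scale `s` — and the objective is the summed absolute mask
difference (symmetric-difference pixel count). No intensity transform is
needed after binarization.

Numerical choices:

* **Rotation/scale center.** The transform equation leaves the center of
  rotation open; we fix it at the centroid of the mask the parameters are
  fitted on (the whole-tissue IR mask) and thread that center explicitly
  through every later warp. Re-deriving the center from whichever mask is
  being warped (e.g. the epithelium-only channel) shifts the result by
  `(I − sR)(Δcentroid)`, which the ~6.5× scale amplifies into tens of
  pixels — a subtle error mode the API is designed to exclude.
* **Initialization.** `s₀ = √(area_ref/area_target)` (or the physical
  pixel-size ratio 6.25/0.9636 ≈ 6.49 when known), translation aligning
  centroids, `θ₀ = 0`.
* **Optimization.** Nelder–Mead with five restarts perturbing θ by
  {0, ±0.1, ±0.2} rad; termination at an absolute objective change < 0.5 or
  2000 evaluations; ties between restarts resolve toward the smallest |θ|.
  The hard objective is integer-valued and piecewise constant, so the
  optimizer minimizes a continuous surrogate in which the warped mask is
  sampled with linear interpolation; the reported objective is always the
  hard count. For references larger than ~400 px the multi-start search
  runs on a 2× subsampled grid and the winner is polished at full
  resolution; parameters are always reported on the full grid.

On synthesized mask pairs with transforms in the capture range
(|t| ≤ 8 px, |θ| ≤ 0.1 rad, s within 5% of the auto-init), parameters are
recovered within (2 px, 2 px, 0.02 rad, 2%).

## Segmentation

**Complete lumens** are white connected components (all channels > 200,
4-connectivity) strictly inside the tissue, kept when (a) at least
`epi_adjacency_frac = 0.3` of their 3-px boundary ring lies on registered
epithelium, (b) the area is within [30, 50 000] px, and (c) solidity ≥ 0.7.

**Incomplete lumens** (cut open by the sample edge) model the sample as the
minimum enclosing circle of the tissue mask. Candidates are the parts of
the border-connected white background that fall inside the circle *and*
within `edge_lumen_reach = 30` px of epithelium; a 3-px morphological
opening detaches them from the thin slivers between the irregular tissue
outline and the fitted circle. The epithelial-adjacency test counts only
the ring portion on tissue (the rest of an edge lumen's boundary faces open
background by construction). Crescent-shaped fitting artifacts are
rejected when the component centroid sits beyond `0.85·radius` *and* the
component is an elongated thin arc (radial thickness < 0.2·radius and
arc-length/thickness > 4); compact notches pass even when shallow.

**Nuclei.** Per-channel Gaussian smoothing (σ = 1 px) and CLAHE
(clip 0.01, tile 64 px) precede the colour score `|R + G − B|`, which is
low on blue (hematoxylin-rich) nuclei and high on pink cytoplasm and white
space. The score restricted to the epithelial neighbourhood (epithelium
dilated by 6 px — the IR grid is ~6.5× coarser than the H&E grid, so the
registered mask carries that much spatial slack) is thresholded at the
*lowest cut of a 3-class Otsu*: the within-epithelium histogram is
trimodal (nuclei / cytoplasm / white), and a plain 2-class Otsu lands
between cytoplasm and white on low-cellularity samples, flooding the
detector with cytoplasm. Closing (disc r = 2) fills holes; a watershed
seeded at distance-transform maxima (min separation 5 px) splits touching
nuclei; components are rejected outside area [15, 500] px, above
eccentricity 0.97, or above mean score 150.

All constants live in `SegmentationConfig` with the defaults above; they
are this package's own calibration of qualitative criteria (size, shape,
epithelial context) and are exposed in the pipeline TOML config.

## Features

Seventeen quantity categories — eight epithelium-related (epithelium area,
nucleus areas, nucleus count, nucleus→nearest-lumen-boundary distance,
nucleus→epithelium-boundary distance, isolated-nucleus count with a 30 px
neighbour radius, far-from-lumen count with an 80 px cut, spatial entropy
of nucleus centroids) and nine lumen-related (area, count, roundness,
distortion, minimum-bounding-circle ratio, convex-hull ratio, boundary and
area symmetry indices, lumen–cytoplasm association).

Each category is aggregated **globally** (AVG/STD and, for counts and
sizes, TOT over the whole sample) and **locally**: a 100×100 px window
slides at stride 50 (windows with < 30% tissue coverage are skipped), the
within-window AVG or TOT is computed per category, and the STD/MIN/MAX of
those window values become the local features. Windows without supporting
objects contribute 0. The default registry fixes 29 global + 38 local = 67
features; the assignment ships as a versioned JSON and is swappable. For
local lumen size, the window total counts only the lumen pixels inside the
window (a partial-area option), while the window average uses whole-lumen
areas of lumens whose centroid falls inside.

Descriptor definitions and their numerical care:

* **Roundness** is `L_peri² / (L_area · r)` with `r = √(L_area/π)`,
  implemented literally even though it is scale-dependent (a disc of
  radius R scores 4π/R); normalizing it away would change the statistic.
  The perimeter uses the Crofton estimator with 4 directions, which is
  nearly unbiased on smooth rasterized contours; crack-length-style
  estimators overestimate disc perimeters by ~5%, i.e. ~10% on the squared
  perimeter.
* **Distortion** is STD/AVG of centroid-to-boundary-pixel distances
  (single-pixel objects return 0 by convention).
* **Minimum-bounding-circle ratio** uses the circle enclosing the pixel
  *squares* (corner points, via Welzl's algorithm on the convex hull), so
  it is always ≥ 1 and dominates the convex ratio.
* **Convex-hull ratio** uses the hull of pixel centers, clamped at 1:
  center-based hulls carry a −O(1/R) half-pixel bias that would otherwise
  push convex shapes below 1.
* **Symmetry indices** reflect the pixel set across the principal axis
  (major eigenvector of the coordinate covariance) through the centroid and
  report the normalized symmetric difference of boundary sets and of areas
  (0 = symmetric, bounded by 1). **Lumen–cytoplasm association** is the
  cytoplasm-rich fraction (R > B vs B ≥ R) of the epithelial pixels in the
  lumen's 3-px boundary ring. Both are this package's concrete definitions
  of quantities whose published definitions are not available in detail;
  they are pinned by fixture tests.
* **Spatial entropy** is Shannon entropy of centroid counts over an 8×8
  grid spanning the tissue bounding box, normalized by log of the number of
  grid cells that contain tissue, so 1 means "uniform over the available
  tissue" and 0 means fully clustered.
* **Missing policy.** Samples (or windows) with no supporting objects get
  the sentinel 0 for the affected features, and the vector carries a
  `missing_policy_applied` flag; no NaN ever reaches the classifier.

## Feature selection

Stage 1 — **mRMR**, difference (MID) form: features are discretized into 3
bins at mean ± 1 SD; the greedy order maximizes
`I(f; y) − mean_{g∈chosen} I(f; g)` (mutual information in bits, plug-in
estimate), ties toward the lower column index. The candidate set is the
top-*i* prefix (*i* ≤ 30) with the best cross-validated AUC, ties toward
the smaller prefix.

Stage 2 — **SFFS**: repeatedly add the feature whose inclusion maximizes
the AUC, then keep deleting the feature whose removal strictly improves on
the best AUC seen; stop at AUC = 1.0 or after 20 additions + deletions;
return the best set encountered. The AUC criterion is 5-fold stratified CV
on the training split with a fixed seed, so selection is deterministic per
training set; all AUC ties break toward smaller sets, then lexicographic
indices.

On 8-feature synthetic tables (n = 120, three informative features at
effects 1.2/1.0/0.8 SD), the SFFS result comes within 0.02 of the
exhaustive best-subset AUC in ≥ 90% of seeded trials; the residual gap is
mostly winner's-curse noise in the exhaustive maximum over 255
cross-validated values.

## Classification and evaluation

RBF-SVM, `K(xᵢ,xⱼ) = exp(−γ‖xᵢ−xⱼ‖²)`, γ = 1 by default with the grid
{10, 1, 0.1, 0.01, 0.001} exposed. Class imbalance is handled by the cost
ratio `C⁺/C⁻ = #neg/#pos`, equalizing the potential total cost of false
positives and false negatives. Features are z-scored with training-split
statistics before the kernel: the feature vector mixes pixel areas,
distances, ratios and entropies, and an RBF on raw columns would be
dominated by the largest unit.

Evaluation is repeated stratified K-fold cross-validation (K = 10): in
every fold the *entire* two-stage selection runs on the training split
only, the SVM is trained on it, and the held-out fold is scored once.
Held-out scores are pooled into one ROC per repeat; the report carries
mean/std over repeats of the AUC and of specificity at 90/95/99%
sensitivity, the latter taken at the highest threshold reaching each
sensitivity level (the conservative, attainable operating point). A pinned
fold split makes the no-leakage contract directly testable: corrupting
held-out labels changes neither the selected features nor the scores.
Train-on-one-cohort/test-on-another transfer uses the same machinery with
selection and standardization statistics from the training cohort only.

## Synthetic data

The generator renders paired H&E-like images (320×320 px) and IR-like label
maps with full ground truth. A tissue core is a star-convex blob (radius
142 px, 7% radial irregularity — real cores are not perfect discs, and the
outline irregularity is precisely what lets binary-mask registration pin
down rotation). Glands are star-convex lumens wrapped in epithelial rings;
nuclei are ellipses (axis ratio 0.72) placed in epithelium with
non-overlap spacing; compartment colours are flat H&E hues (stroma
238/178/208, cytoplasm 226/152/196, nuclei 72/64/150, lumens white) plus
Gaussian noise (SD 6) and an optional stain-shift offset. The IR map is
sampled on a ~6.5× coarser grid through a randomly jittered similarity
transform (scale ±2%, rotation ±0.05 rad, translation ±4 px), so
registration is genuinely exercised end to end.

Class presets encode the canonical morphological contrasts:

| parameter | benign | cancer |
|---|---|---|
| glands | 6 | 14 |
| lumen radius (mean ± SD, clip) | 20 ± 5 px, [11, 30] | 9 ± 2.5 px, [4.5, 14] |
| lumen shape distortion | 0.22 | 0.07 |
| epithelial ring width | 10 px | 8 px |
| nuclear density / 1000 px² | 5 | 10 |
| nucleus radius (mean ± SD) | 3.0 ± 0.3 px | 3.6 ± 0.4 px |
| epithelial foci without lumen | 0 | 3 |

i.e. cancer has many small round lumens, denser and larger nuclei, and
epithelial foci with no lumen at all (nuclei far from any lumen). Effect
sizes are large by design — the cohort is calibrated so a competent
pipeline should reach AUC ≳ 0.95 in 10-fold cross-validation — so passing
tests demonstrate that the geometry, bookkeeping and no-leakage contracts
are right, *not* that the method attains any particular accuracy on real
tissue. Features of real slides the generator does not emulate: stain
texture within compartments, stromal/inflammatory nuclei, touching gland
rings with shared epithelium, folds and edge staining artifacts, and the
IR classifier's own error modes.

## Problem sizes used in the test suite and acceptance script

Rendered-cohort evaluation uses 60 benign + 60 cancer samples at 320×320 px
with 10-fold CV (2 repeats; 1 repeat for the permutation null);
segmentation recovery is scored on 20 of those renders; registration
recovery on 20 synthetic 120×120 mask pairs; the selection oracle on 50
8-feature tables with n = 120. These sizes are the package's choice of a
desk-scale experiment.

## Known limitations

* The circle model for incomplete lumens inherits the minimum-enclosing
  circle's sensitivity to outline irregularity; the epithelium-reach clip
  bounds but does not eliminate the extra background area attributed to an
  edge lumen.
* The symmetry, association and entropy definitions are surrogates pinned
  by tests, not reproductions of unavailable published formulas.
* Registration assumes a similarity transform; real serial sections can
  deform non-rigidly.
* The mutual-information estimates use plug-in histograms with 3 bins; with
  very small training folds the mRMR order is noisy (the SFFS stage is the
  corrective).
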