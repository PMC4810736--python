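# Methods

This note documents the models and numerical choices behind each stage,
what the synthetic generator does and does not emulate, and the known
limitations. It states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Synthetic cell model

A cell outline is a star-shaped polygon built from an ellipse with a
random radial perturbation:

    p(t) = R(φ) · (a cos t, b sin t) · (1 + ε(t)),    t ∈ [0, 2π)

with 256 vertices, a random rotation φ, and

    ε(t) = Σ_{m=2}^{H+1} (c_m cos mt + s_m sin mt),
    c_m, s_m ~ N(0, α²/H),

so the RMS radial perturbation is the `roughness_amplitude` α. Modes m = 0
and m = 1 are excluded: the zeroth mode is an area change (controlled
separately) and the first is translation-like. The factor (1 + ε) is
clipped below at 0.1, which keeps the polygon star-shaped about its centre
and therefore simple; validity is still verified with shapely and a draw
is rejected and resampled on failure (error after 100 rejections).

Cell area and aspect ratio are drawn lognormally with the specified mean
and coefficient of variation (positive support; a normal would go negative
at the CVs used). After perturbation the polygon is rescaled so its
shoelace area equals the drawn area exactly; population mean area is then
an exact generator parameter rather than an approximate one, which makes
Monte-Carlo convergence tests and round-trip recovery tests sharp.

This is the smallest model that moves the five descriptor families
independently: mean area (size), aspect ratio (elongation), roughness
amplitude (boundary and radial variability), nucleus area fraction
(nuclear size), and the nucleus inherits elongation (nuclear shape).

### Population defaults

The low-metastatic baseline is `mean_area` = 4000 px², `area_cv` = 0.25,
`mean_aspect_ratio` = 1.6, `aspect_ratio_cv` = 0.15,
`roughness_amplitude` = 0.06 with 6 harmonics, and
`nucleus_area_fraction` = 0.22 — values typical of well-spread adherent
cells imaged at ~0.5 µm/px. The presets multiply the baseline:

| preset | area | aspect ratio | roughness |
|--------|------|--------------|-----------|
| type1 (high vs low) | ×0.693 | ×1.19 | ×5/3 |
| type2 (high vs low) | ×2.0 | ×0.85 | ×0.7 |

The type-1 multipliers are the pooled effect sizes reported for the
smaller/elongated/rougher pattern (a 30.7% area reduction and ~19%
elongation). The type-2 magnitudes are qualitative: the direction
(larger, rounder, smoother high-met cells, with area roughly doubling on
some surfaces) is reported, but per-surface magnitudes are not printed, so
×2.0 / ×0.85 / ×0.7 were fixed once as representative values and are
recorded in every experiment's metadata.

### Rendering

Each field of view carries three 16-bit planes: nucleus (a concentric
ellipse scaled from the cell's moment ellipse to `nucleus_area_fraction`
of its area), actin (cell interior at 0.6× foreground), and membrane (a
3-px boundary band at full foreground), on a constant background (2000)
with additive Gaussian noise (sd 300) clipped to [0, 65535]. Cells are
placed by rejection sampling so that bounding discs do not overlap and no
cell enters the border margin — every synthetic cell is isolated by
construction. For rough outlines the nucleus ellipse is intersected with
the cell mask, so its realized area can fall slightly below the nominal
fraction (the mean stays within a few percent).

What the generator does **not** emulate: optics (PSF, vignetting, depth),
cell–cell contact, mitosis, texture within compartments, illumination
gradients, or segmentation-adversarial artifacts. Passing tests therefore
demonstrate that the measurement and inference chain is correct on images
whose ground truth is known — not that segmentation is robust to the
pathologies of real micrographs.

### Fast path

`single_cell_instances` renders each cell alone, noise-free, on a tight
per-cell canvas and returns mask pairs directly. Population-level
statistical studies (null calibrations, effect-recovery checks) use this
path; the image-formation + segmentation chain is exercised separately.
The test suite and examples use 60–100 cells per line, matching the study
design of 100 cells per line per surface.

## Image processing

The chain is: per-channel contrast stretch → pixelwise max of actin and
membrane → one 3×3 grayscale erosion → threshold → label → hole-fill →
select → pair nuclei.

- **Contrast stretch** maps the [low, high] percentile range linearly onto
  [0, 65535]. Defaults are (1, 99.9): the nucleus channel's signal can
  occupy under 1% of pixels, and a 99th-percentile ceiling would clip the
  entire signal mode and leave Otsu thresholding noise. A constant plane
  maps to zero.
- **Erosion** uses a 3×3 square structuring element applied once to the
  combined grayscale image before thresholding ("sharpen edge
  boundaries"); the nucleus plane is thresholded without erosion.
- **Thresholding** is Otsu by default with a fixed-value override for
  reproducibility studies; the threshold used is recorded per cell. An
  all-equal plane raises an error directing the user to the fixed method.
- **Selection**: 8-connectivity, holes filled, components touching the
  border margin or below `min_area` (200 px) discarded. Bounding boxes are
  0-based (row, col, height, width).
- **Nucleus pairing**: a nucleus is assigned to the unique cell component
  containing its centroid; cells with exactly one nucleus survive, all
  others are discarded and counted in the log. Watershed splitting of
  touching cells is deliberately out of scope — the analysis is defined
  on isolated cells.

## Morphometry

Boundaries are traced by marching squares at the 0.5 level (sub-pixel,
closed, counter-clockwise). The perimeter is the arc length of the traced
polygon after a circular moving-average smoothing (window 5): raw
marching-squares contours carry half-pixel staircase corners that inflate
perimeter and deflate circularity, and with smoothing a rasterized disk
scores circularity ≈ 1, which anchors the scale of the ratio descriptors.
Areas are pixel counts; the moment ellipse uses the 4·√(eigenvalue)
convention on the pixel-coordinate covariance (a disk of radius R measures
major = minor = 2R); the convex hull comes from Qhull; the minimum
enclosing circle is an exact Welzl solution (containment tolerance 1e−9).
Radial CVs use the population standard deviation (divide by n) over radii
sampled at every contour vertex, without resampling.

Degenerate cases: an empty mask, a single-pixel mask (for the moment
ellipse), collinear hulls, and zero denominators raise typed errors; a
cell whose primitives fail is skipped with a logged reason rather than
aborting the table. Units are pixels unless `pixel_size` metadata is
present, in which case lengths scale by it and areas by its square.

The 29-descriptor roster (21 cellular + 8 nuclear) is exported as a JSON
schema next to every feature CSV, and the descriptor list is an importable
constant, so the roster is visible configuration: descriptors named in the
source analyses (area, axes, aspect ratio, solidity, circularity, the two
radial CVs, nuclear size and shape) are fixed, and the remainder are
standard region measurements chosen to complete the count.

## Statistics

- **Welch t-test**: unequal variances, Welch–Satterthwaite df, two-tailed;
  sample standard deviations use n−1. Identical constant samples return
  t = 0, p = 1; zero variance in both samples with different means is an
  error.
- **Holm**: sort p ascending, reject while p(i) ≤ α/(m−i+1), stop at the
  first failure. Never less conservative than unadjusted testing, never
  more than single-step Bonferroni.
- **Percent difference** = 100 · (mean_high − mean_low)/mean_low; the
  low-metastatic mean is the baseline.
- **PCA**: columns z-scored (n−1), SVD, variance fractions from squared
  singular values. Constant columns are dropped with a warning rather than
  failing the run; fewer than four non-constant columns is an error.
- **NMDS**: Kruskal stress-1 minimized by nonmetric SMACOF — isotonic
  regression of configuration distances on the dissimilarities, then a
  Guttman-transform update — with one principal-coordinates start plus
  random starts (defaults: 8 starts in the pipeline, max 500 iterations,
  tol 1e−7 on the stress decrease). The best start is kept;
  non-convergence flags the result instead of raising. Configurations are
  centred and rotated to principal axes before export (rigid, so
  distances are preserved). k = 3 follows the source design; no k
  selection is performed.
- **PERMANOVA**: SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within summed per group,
  R² = 1 − SS_within/SS_total, pseudo-F from the one-factor decomposition,
  p by label permutation with the +1 correction (default 999
  permutations, seeded).
- **Confidence ellipses**: per-group covariance ellipse at the χ²(2)
  quantile — a 95% region of the fitted Gaussian, used for plotting.

## Classification

The network is d → H (tanh) → 1 (logistic) trained on cross-entropy.
SCG follows Møller (1993): a conjugate-gradient scheme with a
Levenberg–Marquardt-style scaling parameter in place of a line search;
the objective is non-increasing across accepted steps. Initial weights
are uniform in ±1/√(d+1) from the spec seed. Because tiny tanh networks
have symmetric stationary points (the classic XOR plateau at loss
ln(2)/2), training runs 3 seeded restarts by default and keeps the lowest
final loss. A plain gradient-descent optimizer (`optimizer="gd"`) exists
to cross-check that conclusions do not depend on the optimizer.

Protocol: stratified 50/25/25 train/test/validation split. Model selection
repartitions only the train+test pool (validation is never touched — a
test asserts the standardization statistics and selection see no
validation row), scores each candidate by mean test accuracy, and breaks
ties toward fewer hidden units, then fewer features. The default candidate
family is the full 29-descriptor model at hidden widths {2, 5, 10} with 3
repartitions; a greedy forward feature-selection helper
(`greedy_forward_selection`) is provided for explicit attribute search,
since exhaustive search over 2²⁹ subsets is intractable. The winner is
refit on train+test and evaluated once on validation.

Sample-level calling: 100 paired samples of 10 cells, each sample drawn
without replacement within itself and independently across pairs (a
25%-validation pool cannot supply 100 disjoint samples), P = fraction
predicted high-metastatic, called high iff P > 0.6 strictly (P = 0.6 is a
low call). Reports tally TP/TN/FP/FN over all 2×100 samples with
accuracy = (TP+TN)/total, FNR = FN/(FN+TP), TPR = TP/(TP+FN); FNR + TPR
= 1 identically.

## Pipeline and seeding

One global seed fans out through `numpy.random.SeedSequence` into
independent child seeds for generation, partitioning, NMDS starts,
permutations, and sampling, so each stage is independently reproducible
and a rerun of the same config is bit-identical. Every run directory
contains a manifest (config, child seeds, package version, completed
stages) and a log; a stage failure preserves earlier artifacts and records
the failing stage.

## Problem sizes

Defaults were chosen to mirror the study design at desk scale: 100 cells
per line per surface; 20,000 replicates for power and type-I-error
simulations; 999 permutations for PERMANOVA in the pipeline (199–999 in
examples); 500 random point sets for the geometry oracles; 200
simulations for the PERMANOVA null-calibration check.

## Limitations

- The generator's noise model is additive Gaussian on a constant
  background; Otsu behaves differently under heavy-tailed or structured
  noise.
- Segmentation assumes isolated cells; touching cells are discarded, not
  split.
- NMDS stress values and PERMANOVA R² on real data depend on the data;
  only algorithmic correctness (oracle agreement, calibration, descent,
  recovery on embeddable configurations) is testable here.
- The type-2 preset magnitudes are representative, not fitted.
- Greedy forward selection is a heuristic; it can miss interacting
  feature subsets.
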