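# cytoshape

Quantitative cell-shape morphometrics for paired low-/high-metastatic cell
lines, built for studies that ask whether metastatic capacity leaves a
measurable signature in single-cell morphology. The package takes
multi-channel fluorescence micrographs (nucleus / actin / membrane), or
fully synthetic images from its built-in generator, and carries them
through segmentation, shape measurement, statistics, ordination, and
machine-learning classification — every stage seeded and reproducible.

It is aimed at cell biologists and image analysts who want the complete
chain as tested library code rather than a pile of one-off scripts.

## What it computes

**Segmentation** (`cytoshape.imgproc`). Per-channel contrast stretching,
pixelwise max of the actin and membrane channels, one 3×3 grayscale
erosion, Otsu (or fixed) thresholding, 8-connected labelling with hole
filling, rejection of border-touching and undersized components, and
pairing of each cell with the nucleus whose centroid it contains.

**Morphometry** (`cytoshape.morphometry`). 29 descriptors per cell — 21
cellular, 8 nuclear — covering projected size (area *A*, equivalent
diameter √(4A/π), bounding box), elongation (moment-ellipse axes, aspect
ratio = major/minor, eccentricity), boundary shape (perimeter *P*,
circularity 4πA/P², roundness 4A/(π·major²)), convexity (convex hull area
and perimeter, solidity A/A_hull, extent), and radial variability,
including two coefficients of variation of boundary radii:

- **CV Rad Hull** — sd/mean of radii from the convex hull centroid to the
  cell perimeter;
- **CV Rad Circle** — sd/mean of radii from the minimum-enclosing-circle
  centre (exact Welzl solution) to the hull vertices.

**Statistics** (`cytoshape.stats`). Welch's unequal-variance two-tailed
t-test per descriptor with Holm step-down control of the family-wise error
over the 29 tests; percent differences relative to the low-metastatic
mean; PCA by SVD of z-scored descriptors; nonmetric multidimensional
scaling (k = 3) of Bray–Curtis dissimilarities on max-relativized
descriptors, minimizing Kruskal stress-1 with isotonic-regression /
Guttman-transform iterations from a principal-coordinates start plus
random restarts; PERMANOVA R² (proportion of distance variation explained
by group) with a permutation p-value; and 95% confidence ellipses for
ordination plots.

**Classification** (`cytoshape.classify`). A one-hidden-layer perceptron
(tanh hidden units, logistic output, cross-entropy objective) trained with
Møller's scaled conjugate gradient. Data are split 50/25/25 into
train/test/validation, stratified by class; model structure is chosen by
average test accuracy over repeated train/test repartitions, the winner is
refit on train+test and scored once on the untouched validation set.
Sample-level calling emulates a biopsy: draw paired 10-cell samples,
compute the fraction *P* predicted high-metastatic, call the sample
high-metastatic iff *P* > 0.6.

**Synthetic data** (`cytoshape.synthetic`). Cells are star-shaped polygons
(ellipse radius modulated by a random low-order Fourier series) rendered
into noisy 16-bit three-channel frames with non-overlapping placement. Two
presets encode the reported effect patterns: `type1` (high-met cells
×0.693 in area, ×1.19 in aspect ratio, rougher boundary) and `type2`
(larger, rounder high-met cells).

## Worked example

Run the full pipeline on a synthetic type-1 paired experiment, 100 cells
per line:

```bash
cytoshape run-all --preset type1 --n-per-line 100 --seed 7 --out runs/demo
cytoshape report runs/demo
```

Output from this exact invocation (abridged):

```
## Pairwise comparisons (Welch + Holm)
27/29 descriptors significant after Holm correction:

- area: -31.9% (high vs low), p = 1.19e-16
- aspect_ratio: +26.9% (high vs low), p = 2.19e-18
- cv_rad_hull: +50.1% (high vs low), p = 1.43e-25
...

## Ordination
- NMDS stress (k=3): 0.0429
- PERMANOVA R^2 = 0.307, p = 0.0010 (999 permutations)

## Classification
- single-cell validation accuracy: 0.860
- sample-level accuracy (10-cell samples, threshold 0.6): 1.000
  (TP=100, TN=100, FP=0, FN=0; FNR=0.000, TPR=1.000)
```

Reading this: the generator planted a −30.7% area effect and a +19%
aspect-ratio effect; the measured −31.9% and +26.9% recover them (aspect
ratio reads higher than the planted mean ratio because boundary roughness
adds elongation variance). Nearly every descriptor separates the groups
after Holm correction at these effect sizes, the ordination shows the two
populations overlapping but distinct (R² = 0.31), single cells classify at
86%, and 10-cell samples classify essentially perfectly — the same
qualitative pattern seen in paired osteosarcoma lines.

The stages are also available individually (`generate`, `segment`,
`measure`, `compare`, `ordinate`, `classify`), all driven by the same YAML
config, and as plain library functions.

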