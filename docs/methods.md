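# Methods

`phenoprof` implements a high-content-screening analysis chain: two-step
seeded-watershed cell segmentation, decomposition of each cell into eight
subcellular regions, combinatorial single-cell feature extraction, and
construction and evaluation of phenotypic profiles (mean, PCA, and SVM-based
d-profiles). This note records the models, the parameter choices that
matter, and the limits of what the synthetic-data tests demonstrate.

## Segmentation

**Step 1 — nuclei.** The DNA channel is Gaussian-smoothed
(`smoothing_sigma`, default 2 px), then background-flattened with an h-dome
transform: `hdome(f, h) = f − R_f(f − h)`, where `R` is grayscale
morphological reconstruction by dilation. The dome image is thresholded
with Otsu's method (256-bin histogram over the value range, foreground
strictly above the threshold), holes are filled, and candidate components
are kept only if their mean Laplacian-of-Gaussian response at the nuclear
scale (`log_sigma`, default 5 px) is negative — bright blobs respond
negatively at the matched scale, flat bright debris does not. Touching
nuclei are split by a watershed on the negated Euclidean distance
transform, seeded at the regional maxima of the distance map after light
smoothing (sigma 1 px).

Parameter choices worth explaining:

- **Auto h = 80% of the smoothed plane's dynamic range.** The dome
  transform keeps only the top `h` of each local maximum. A small `h`
  (a few percent of the range) turns nuclei into thin peak caps and the
  subsequent Otsu threshold then retains only the brightest crowns; mask
  fidelity against ground truth collapses. With `h` near the full signal
  amplitude, the dome contains the whole nuclear bump while still removing
  any background pedestal that varies more slowly than the blob scale. A
  sweep over {0.5, 0.7, 0.8, 0.9, 0.95} of the dynamic range on independent
  ground-truthed scenes gave the best worst-case nuclear Jaccard (0.86) at
  0.8. For images with strong uneven illumination a smaller explicit `h`
  remains available in the configuration.
- **Component-level (not pixel-level) LoG gating.** Inside a flat bright
  blob the LoG response is ~0 plus noise, so demanding `LoG < 0` per pixel
  punches random holes in nuclear interiors and erodes boundaries. Gating
  whole candidate components on their *mean* response keeps the operator's
  purpose (reject flat debris) without degrading blob extent.
- **Contrast guard.** If the mean foreground-minus-background contrast of
  the smoothed plane is below `min_contrast_snr` (default 5) background
  standard deviations, the frame is declared empty. Otsu's criterion
  always produces a threshold, even on pure noise; the guard is what makes
  "no cells in this frame" a reachable, correct answer.

**Step 2 — cells.** A composite image is formed as a weighted sum of
channels (default: equal weights over non-DNA markers, 0 for DNA, since
cell bodies are delineated by cytoplasmic stains), smoothed, and Otsu
thresholded; the foreground is united with the nuclear pixels and
partitioned by a seeded watershed flooding the inverted composite from the
nuclei (4-connected flow). Each basin inherits its nucleus' label, so
nucleus count equals cell count and each nucleus lies inside its cell —
both are asserted invariants. Cells below `min_cell_area` (default 100 px)
are removed together with their nuclei; border-touching cells are kept by
default (`border_policy: remove` switches). Ridge assignment follows
scikit-image's deterministic flooding order; we assert determinism and
basin disjointness rather than any particular ridge convention.

## Subcellular regions

For each cell the eight regions are derived from the cell and nucleus
masks with disc structuring elements: inner nucleus = nucleus eroded by
`w_nb` (default 2 px); nuclear boundary = the complementary band;
peri-nucleus = nucleus dilated by `w_pn` (default 4 px), clipped to the
cytoplasm; cytoplasmic boundary = the inner rim of the cell of width
`w_cb` (default 3 px) restricted to cytoplasm minus the peri-nuclear band
(peri-nucleus wins where the bands overlap, making the three cytoplasmic
subregions an exact partition of the cytoplasm); inner cytoplasm = the
remainder. The partition, nesting and disjointness identities are checked
by `RegionMasks.validate()` on every derivation. Widths are in pixels;
band areas are monotone in their widths.

## Features

A feature is named `<type[_submeasure]>:<markers>:<regions>`, e.g.
`fraction_total_intensity:ERK:dna_region-cell_region`. Morphology
features carry no marker and render with an empty marker segment.
Configuration expands deterministically: intensity features as the full
marker x region cross product (7 summary statistics: total, mean,
population SD, median, MAD, min, max); morphology per region (8 measures:
area, perimeter, form factor 4πA/P², eccentricity, solidity, equivalent
diameter, major/minor axis lengths); total-intensity ratios over all
ordered pairs of distinct selected regions, per marker and per explicitly
listed marker pair; fractions of total intensity only over nested region
pairs (numerator region a subset of the denominator region by
construction), so those features are guaranteed to lie in [0, 1]; pixel
correlations (Pearson) over unordered marker pairs per region. Undefined
values (empty region, zero denominator, constant intensity vector) are
NaN, exported to CSV as `NA`. Intensities are used as stored; background
subtraction is out of scope.

The morphology and intensity sub-measure catalogs are this package's own
fixed inventory. Feature counts therefore depend on the configuration, not
on any external feature list.

## Profiles

- **Mean profiles** average each feature over a treatment's cells (NaNs
  excluded per feature), on the features as stored.
- **PCA profiles** take the treatment x feature matrix of mean profiles
  (computed on control-standardized features), centre it, and keep the
  smallest number of leading principal components whose cumulative
  explained variance reaches 95%; each treatment's score vector is its
  profile. PCA is computed at the treatment level because the contract is
  one profile per treatment; cell-level PCA would require an additional,
  unspecified aggregation step.
- **d-profiles** z-score all features by the negative-control population's
  mean and SD (zero-variance features dropped; features undefined in >10%
  of cells dropped, remaining NaNs imputed with the control median), then
  fit an L2-regularized squared-hinge linear SVM in the primal
  (treated = +1, control = −1, C default 1.0, tolerance 1e-6,
  class-balanced weights) per treatment. The profile is the unit normal of
  the separating hyperplane; the intercept is excluded. Standardization is
  what makes weight magnitudes comparable across features; it can be
  switched off.

## Evaluation criteria

- **Boundary error**: mean Euclidean distance from each boundary pixel of
  the reference mask to the nearest boundary pixel of the automated mask.
  Boundary pixels are foreground pixels with a 4-neighbour outside their
  label or on the image edge. The statistic is asymmetric
  (reference → automated) by definition; a symmetric average is available
  behind a flag. Distances come from an exact Euclidean distance
  transform. Note that for discrete pixel boundaries a rigid 1-px
  translation of an object does *not* cost 1.0: boundary runs parallel to
  the shift still coincide with the shifted boundary set, so e.g. a
  translated square scores 0.5.
- **Rand error**: 1 − (c + d)/C(N,2) over pixel pairs, where c counts
  pairs co-labelled in both masks and d pairs separated in both. The
  background is included as one region so the statistic is a proper
  partition distance; `ignore_background` restricts pairs to
  reference-foreground pixels.
- **Profile dissimilarity**: cosine dissimilarity d(g,h) = 1 − cos(g,h).
  `intra_group` averages, over groups, the maximum pairwise within-group
  dissimilarity. `inter_group(n)` sorts the cross-group dissimilarities of
  every *ordered* group pair, averages the n smallest, and scales the sum
  by 2/(N(N−1)); because each unordered pair is visited twice, the
  statistic equals *twice* the mean over unordered pairs. This doubled
  form is implemented as printed in the field's definition; it is a
  monotone scaling, so comparisons between profiling methods are
  unaffected.

## Synthetic data

**Scenes** place elliptical cells (semi-axes 13-17 px, axis ratio
0.75-1) with concentric elliptical nuclei (semi-axes 6-9 px) in a
256 x 256 16-bit frame, rejection-sampling centres so that cells are
disjoint (an `overlap` parameter deliberately relaxes this). DNA renders
bright in nuclei (8000 counts ± 15% per cell), cytoplasmic markers bright
over cell bodies (3000 counts ± 20%), over a 200-count background, with a
1-px Gaussian PSF and 100-count Gaussian read noise — a moderate-noise,
well-stained monolayer. Ground-truth masks are returned alongside. What
these scenes do **not** model: uneven illumination, intensity textures,
irregular morphologies, confluent sheets, debris and imaging artifacts.
Passing the recovery tests (exact count recovery, mean boundary error
≤ 2 px, mean Rand error ≤ 0.05 on 20-cell scenes) therefore demonstrates
the correctness and stability of the algorithmic chain, not
state-of-the-art accuracy on difficult real images.

**Populations** emulate a 32-knockdown siRNA screen: 4 functional groups
x 8 treatments, 200 cells per treatment (≈ 4 frames of ~50 cells), 400
negative-control cells. Of 70 features, each group shifts its own block
of 5 informative features by 4 control-SDs (±10% per-treatment jitter);
the other 50 are nuisance features, identically distributed in every
condition but with 40x the control SD of the informative features — the
high-variance, uninformative features that defeat naive averaging, with a
scale spread well inside what raw image features (areas vs. total
intensities vs. correlations) exhibit. All randomness flows from a single
seed through SeedSequence spawning.

Two honest caveats from our own measurements:

- PCA profiles look *excellent* on these populations (near-zero intra-group
  dissimilarity): the planted group structure is exactly low-rank, so the
  leading components of the treatment-level matrix are the group contrasts.
  Real screens are not low-rank plus isotropic noise; the synthetic data
  support the d-profile-vs-mean-profile comparison, not a three-way method
  ranking.
- All d-profiles of a run share the same negative-control sample, so their
  weight noise contains a common component that moves all cross-group
  dissimilarities coherently; the n-nearest-neighbour inter-group statistic
  consequently fluctuates several times more between runs for d-profiles
  than for mean profiles. The d-over-mean advantage in inter-group
  dissimilarity is positive in expectation at n = 5, 10 and 30 under the
  default conditions, but at n = 30 its per-run margin is of the same order
  as this shared-control fluctuation, so a minority of runs invert the
  ordering there. Enlarging the control population would shrink the shared
  component.

## Numerical conventions

Coordinates are row-major, 0-based, pixel-centred; centroids are unweighted
means of member pixel coordinates. Objects are 8-connected; watershed flow
is 4-connected. Otsu ties resolve to the lowest maximizing level. The
discrete LoG kernel's residual DC gain is subtracted so constant images map
to exactly zero response. Labels are relabelled to 1..K after every public
operation, applied consistently to paired nucleus/cell masks. CSV floats
carry 17 significant digits so re-parsing (with a round-trip-exact parser)
reproduces stored values bit-exactly. Frame jobs are pure functions of
(images, parameters); results are written by a single writer in sorted
(well, frame) order, which is what makes stores bit-identical for any
worker count.

## Problem sizes used in the test suite and acceptance script

Segmentation recovery runs 100 seeded 20-cell scenes; nucleus splitting 20
seeded two-disc frames; metric-oracle comparisons 50 random mask pairs at
≤ 32 x 32 (brute-force pair enumeration is quadratic in pixel count);
profiling comparisons 100 seeded populations at the default design, with
the informative-feature recovery check at a 2-treatments-per-group scaled
design. These sizes keep the full suite in the minutes range while leaving
the statistical bounds meaningful.
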