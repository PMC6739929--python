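# Methods

This note documents the models, conventions, and numerical choices behind
`radiomic`: a pipeline for texture/shape analysis of single 2-D lesion
regions of interest (ROIs), as used for breast-cancer molecular subtyping
on contrast-enhanced MRI. The pipeline stages are: ROI gray-level
normalization, extraction of a fixed 352-feature registry, filter feature
selection per pairwise comparison, and linear-discriminant projection with
k-nearest-neighbor leave-one-out cross-validation (LOOCV). A seeded
synthetic lesion generator provides cohorts with controllable class
differences so every stage is testable without patient data.

## ROI normalization and quantization

Each ROI is normalized independently: with μ and σ the mean and
*population* standard deviation of the masked intensities, the dynamic
range is limited to μ ± 3σ and divided into `n_levels` (default 64)
equal-width bins mapped to gray levels 1..n_levels. This cancels affine
brightness/contrast differences between acquisitions, which is exactly
the invariance the texture features inherit (tested as a property).

Choices:

* **Out-of-range pixels are clipped into the extreme bins, not
  excluded.** Exclusion would change the pixel support seen by geometry
  vs texture; clipping keeps one common support.
* A zero-variance ROI maps every pixel to the middle level ⌈n/2⌉.
* The standardized intensity is rounded at 1e-9 before binning, so an
  exact affine rescaling of the raw image cannot flip a pixel across a
  bin edge through floating-point jitter.
* Histogram (HIS) features are computed on the same quantized levels as
  all other families; one `QuantizedROI` is the single substrate.

## Feature families (352 features)

| Family | n | Substance |
|---|---|---|
| HIS | 9 | mean, variance, skewness, excess kurtosis, percentiles 1/10/50/90/99 of the masked levels |
| COM | 220 | 11 Haralick statistics × 20 offsets `S(dx,dy)` (orientations 0°, 90°, 135°, 45° at distances 1–5) |
| RLM | 20 | 5 run-length statistics × 4 directions |
| GRA | 5 | absolute-gradient moments + nonzero fraction on interior pixels |
| ARM | 5 | causal autoregressive weights θ1..θ4 (W, NW, N, NE) and residual σ |
| WAV | 20 | orthonormal Haar subband energies, 4 subbands × 5 scales |
| GEO | 73 | mask morphometry (below) |

Conventions that matter numerically:

* **COM**: matrices are symmetrized (each unordered pair counted in both
  directions) and normalized; gray levels enter formulas with their
  1-based index. All entropies use the natural logarithm with
  0·log 0 ≡ 0. `SumVarnc` is the variance of the i+j distribution about
  `SumAverg` (Haralick's original text uses the sum entropy in that
  formula; the variance-about-the-mean form is the self-consistent
  reading and is fixed here and in the test oracles). `Correlat` of a
  zero-marginal-variance matrix is defined as 0. A matrix with no valid
  pixel pair is degenerate: all 11 statistics are 0 and a warning is
  logged.
* **RLM**: runs are maximal constant-level segments along masked
  collinear pixels; the mask interrupts runs. `Fraction` = (number of
  runs) / (pixels traversed). The invariant Σ l·r(g,l) = traversed pixel
  count is fuzz-tested.
* **GRA**: central differences at pixels whose four edge-neighbors are
  masked; magnitude √(gx² + gy²); moments use the same zero-variance
  convention as HIS.
* **ARM**: levels are centered on the ROI mean before the least-squares
  fit (the AR model describes fluctuations about the mean; without
  centering the weights absorb the mean level itself and a white-noise
  ROI would not yield θ ≈ 0). Minimum-norm solution when the normal
  system is singular; fewer than 20 eligible pixels ⇒ degenerate zeros.
* **WAV**: the mask bounding box, with non-mask pixels filled by the ROI
  mean, is padded with the ROI mean to the next power of two and
  transformed by the iterated 2-D orthonormal Haar analysis (each 2×2
  analysis vector has unit norm, so a constant ROI of value c has LL
  scale-1 coefficients 2c). A coefficient counts toward its subband
  energy when its support square overlaps the mask; energies are mean
  squared coefficients over counted positions; scales beyond the box
  size are emitted as 0. The subband naming is orientation-explicit: HL
  is high-pass along x, so vertical stripes excite HL, not LH.

## Geometry registry (GEO, 73 features)

The GEO family is a deterministic, documented registry (the upstream
MaZda feature list names the family and its size but not all 73
definitions; this registry preserves the `GeoW*`/`GeoE*` naming so
selected-feature reports read the same way). All features are computed on
the bounding-box crop of the largest 4-connected component, which makes
them translation-invariant by construction:

* size/perimeter: area, edge-count perimeter, circularity, compactness,
  perimeter/area ratios, equivalent diameter;
* moment ellipse: extent, eccentricity, orientation, major/minor axis
  lengths and ratio;
* Feret diameters at 0°/45°/90°/135°, their mean, max, min, and the
  max/min elongation ratio;
* bounding box width/height/aspect;
* radius function r(φ): mean, SD, CV, max, min, span, skewness,
  kurtosis, 10-bin entropy, area ratio A/(π r̄²), and zero crossings of
  r − r̄;
* convexity (area / hull area), hull-perimeter ratio, defect area;
* symmetry overlaps under 180° rotation and horizontal/vertical mirror;
* inscribed radius and distance-transform statistics, thickness ratio;
* `GeoW1..GeoW7`: normalized central moments η20, η11, η02, η30, η21,
  η12, η03; `GeoW8..GeoW14`: the seven Hu invariants;
* `GeoE1..GeoE12`: FFT harmonic amplitudes 1–12 of r(φ) normalized by
  its mean, plus low-order (1–4) and high-order (5–12) sums.

Numerical conventions:

* **Perimeter vs circularity.** `GeoPerimeter` counts exposed pixel
  edges (city-block boundary). That estimator overestimates the length
  of smooth boundaries by a direction-dependent factor, so
  `GeoCircularity` = 4πA/P² uses the Crofton perimeter estimate instead;
  a digital disk then scores ≈ 0.97 rather than ≈ 0.6. The edge-count
  perimeter still feeds the compactness/roughness descriptors, where
  staircase length is the point.
* **Feret diameters** are widths of the convex hull of the pixel-corner
  points, so an axis-aligned w×h rectangle measures exactly w and h, and
  the elongation of a 10×40 rectangle is exactly 4. Max/min are taken
  over the four sampled directions.
* **Radius function**: 360 equal angles from the centroid, radial march
  in 0.25-px steps, outermost crossing kept (ties on the boundary
  resolved outward).

Whether the upstream tool's `GeoW7`/`GeoW9`/`GeoE12` coincide with these
slots cannot be verified from the published material; the mapping here is
deterministic and documented, not a claim of bitwise conformance.

## Feature selection

For a two-group comparison (class vs class, or class vs rest) the subset
size is **one feature per ten samples, rounded to the nearest integer**
(round-half-up, floor 1): n = 91 → 9, 68 → 7, 57 → 6, 31 → 3, 19 → 2.
This nearest-integer reading is the only one consistent with all the
published per-comparison counts; flooring is not.

* **Fisher**: size-weighted between-class variance of class means over
  pooled within-class (population) variance. Zero within-variance with
  distinct means returns +∞, ranking the feature first.
* **POE+ACC** (greedy): the probability of classification error (POE) of
  a feature is the minimum misclassification fraction of a
  single-threshold rule over all cut points and both polarities (for
  more than two groups: the nearest-class-mean rule in 1-D). The first
  pick minimizes POE; pick j+1 minimizes POE + mean |Pearson r| with the
  already-selected set (1:1 weighting). Correlation with a constant
  feature is defined as 0.
* **Mutual information**: the feature is discretized into 10 equal-width
  bins over its observed range; MI with the class label is reported in
  bits. Equal-width binning over the observed range makes MI exactly
  invariant to increasing affine maps.

Ties everywhere break by canonical registry order, so selection is fully
deterministic.

**Protocol fidelity note.** Selection is performed once on all samples of
the comparison, *outside* the cross-validation loop, mirroring the
original study protocol. This is optimistically biased: with 352
candidate features and small cohorts, selection can manufacture apparent
separation from identically distributed classes (the zero-separation
setting of the monotonicity test sits visibly above chance for exactly
this reason). The bias is retained deliberately for fidelity and is
documented rather than silently corrected.

## Classification

Selected features are z-scored, projected onto the generalized
eigenvectors of between-class vs within-class scatter (the "most
discriminating features", MDF), and classified by Euclidean k-NN (default
k = 1) in MDF space. Retention keeps eigenvalues individually exceeding
97% of the eigenvalue sum (floor 1). Eigenvalues are truncated at the
rank bound C−1; a two-group comparison therefore always retains exactly
one MDF. (A published two-MDF case for one pairwise comparison is not
reproducible under the standard two-scatter formulation, whose
between-class rank for two groups is 1; this implementation asserts the
rank bound instead of emulating it.)

LOOCV refits the z-scoring parameters, the scatter matrices, and the
projection on the n−1 training samples of every fold; the held-out sample
never influences its own fold (tested by injecting an absurd outlier as
the held-out sample). The within-class scatter receives a ridge of
1e-6 · trace/dim only when its Cholesky factorization fails. k-NN ties
break by the nearest neighbor, then by lower sample index. Accuracy is
the raw fraction correct (no class balancing), so imbalanced groups can
score high without real separability — as in the original protocol.

Frozen-set validation re-runs LOOCV on a second cohort restricted to a
previously selected feature list, with no re-selection.

## Synthetic cohorts

Each class recipe controls: `correlation_length` (σ of the Gaussian
kernel smoothing a white-noise field, which is then standardized to unit
variance), `contrast_amplitude` (intensity scale of that field),
`noise_sd` (white noise inside the lesion), `elongation` (area-preserving
anisotropic scaling of the base ellipse, axis-aligned), and
`spiculation_amplitude` (boundary perturbation by sinusoids of angular
orders 5–12 with seeded random phases and convex random weights, as a
fraction of the mean radius; ≤ 0.5 keeps outlines star-shaped and hence
simply connected). Lesions sit on a flat background (default 400) with
optional background noise; images are written as 16-bit TIFF, masks as
8-bit PNG, plus a manifest CSV whose receptor columns are filled through
the inverse of the IHC surrogate mapping.

Per-sample seeds derive from `SeedSequence(cohort_seed, class_index,
sample_index)`, so a cohort extends without reshuffling earlier samples.

What the generator emulates: class-dependent interior texture smoothness
and amplitude, outline elongation and spiculation, seeded determinism.
What it does not: MR physics (coil bias, motion, partial volume),
heterogeneous enhancement kinetics, multi-focal lesions, inter-scanner
protocol differences. Passing tests on synthetic cohorts therefore
demonstrate correctness and internal statistical behavior of the
pipeline, not clinical performance on real MRI.

Default problem sizes in the test suite (chosen to exercise the full
pipeline at desk scale): lesions of mean radius 12–18 px in 64–128 px
frames; the separability sweep uses 5 settings × 10 seeds × 20 lesions of
radius 14 in 80-px frames.

## Feature maps

Sliding-window maps evaluate one texture feature on (window ∩ mask)
around each masked pixel, using the normalization parameters of the full
ROI — map contrast then reflects texture, not local renormalization.
Windows with fewer than 16 masked pixels are undefined (missing). GEO
features are global and cannot be mapped. Maps are illustrative only and
are never fed to the classifier. Default window 15 px.

## Known limitations

* The GEO registry and the WAV/ARM conventions are documented choices;
  they may differ numerically from the closed-source binaries used in
  the original study, whose exact formulas are not published.
* Patient-level accuracies from the original cohorts cannot be
  reproduced here: the MRI data are not public. The acceptance checks
  cover the in-protocol arithmetic (registry counts, cohort composition
  identities, subset-size rule) and the statistical behavior of the
  pipeline on synthetic cohorts.
* Selection-outside-CV is kept for fidelity (see above); a
  selection-in-folds variant would be the methodologically conservative
  alternative and is deliberately out of scope of the default protocol.
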