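# Methods

This note documents the models, conventions and design choices behind
the package, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort model

All synthetic data derive from one per-patient latent severity factor
`z_i ~ Normal(0, latent_sd²)`:

| quantity | model | default |
|---|---|---|
| tile nucleus rate | `nuclei_rate_base · exp(nuclei_rate_slope · z)` | 600 / 512-px tile, slope 0.2 |
| radiomics feature j | `a_j · z + Normal(0, noise_sd²)`, `a_j ~ U(loading range)` | loadings ±0.8, noise SD 0.6 |
| OS, PFS (months) | `scale · exp(0.5 z + ε)`, `ε ~ Normal(0, 0.25)` | scales 18 / 8 mo |
| CD8 (%) | `100 · logistic(cd8_slope · z + cd8_offset + ε)` | slope 1, offset −3.0 |
| progression | `Bernoulli(logistic(1.15 − 0.8 z))` | base rate ≈ 0.76 |

Defaults emulate a 36-patient ICI-treated NSCLC cohort: OS spanning
roughly 2–60+ months, PFS shorter than OS, mean CD8 near 7.5 % (the
offset was fitted numerically to the *mean* of the logistic-normal, not
its median), and about three quarters of patients progressing.
Survival is uncensored by default; `censor_horizon` applies
administrative censoring at a fixed month for testing the
">12 months" classification on censored records.

**Tiles.** Nuclei are filled dark-purple ellipses (eccentricity ≤ 2:1,
radii 5–9 px) on pale pink, with mild additive Gaussian noise; the count
is Poisson(rate) and placement is rejection-sampled with a 2-px minimum
separation (≤ 1000 attempts per nucleus, then skip). The palette is
fixed — background ≈ (240, 220, 225), nuclei ≈ (90, 60, 120) — so
Otsu-based steps behave identically across runs. The separation margin
guarantees distinct ground-truth nuclei never fuse into one connected
blob, which keeps "count recovery" well-defined; real H&E nuclei do
touch, so recovery rates measured here do not transfer to real tissue.
The base rate (600 nuclei ≈ 28 % pixel coverage at z = 0, ≥ 16 % at
z = −2.5) represents cellular tumour tissue; it is chosen so that tiles
across the whole latent range pass the pipeline's own ≥ 15 %
nucleus-percentage filter, as real analysed slides must have — a
sparser default would silently drop low-severity patients.

**What the generator does not emulate:** staining variation, scanner
artifacts, nucleus texture/chromatin, stromal vs tumour cell types,
realistic CT feature distributions (radiomics columns are linear-Gaussian
in z), or censoring-informative dropout. Passing recovery tests
demonstrates correctness of the computational chain, not performance on
real slides.

**Determinism.** Every quantity derives from one seed via
`numpy.random.SeedSequence` spawning; per-tile child seeds are stored so
tile images are regenerated lazily and bit-identically on demand.

## Histology preprocessing

Tissue mask: ITU-R 601 luminance → Otsu threshold, tissue = darker
class → dilation (disk r = 2) → fill holes < 256 px → remove objects
< 1024 px. All sizes are configurable; the defaults are working-resolution
choices, not protocol values. Two guards: a fully uniform image (Otsu
undefined) yields an empty mask with a warning; and if the brighter Otsu
class is not near-white (mean < 245/255) the frame contains no slide
glass — glass scans near-saturated — so the whole frame is tissue.
Without that guard, darker-side Otsu on a frame entirely inside tissue
would keep only the nuclei.

Patching: non-overlapping grid from (0, 0), partial edge tiles dropped,
keep tiles with within-tile mask mean ≥ 0.8 (row-major). The original
workflow used a score-ranking tiler; since all qualifying patches were
extracted, exhaustive grid + threshold is equivalent in coverage and
simpler to reason about. The stride choice (non-overlapping) is ours and
is recorded in the run config.

Nucleus score: fraction of pixels classified as nucleus by the same
classifier that seeds the watershed — hematoxylin channel of the HED
colour deconvolution, Otsu threshold (nuclei = high optical density),
opening with disk r = 1. A dynamic-range guard (< 0.05 OD) treats flat
patches as nucleus-free, since Otsu on pure noise would split it in
half. Patches with score ≥ 0.15 are retained (inclusive, per the
"15 % or higher" rule).

## Watershed segmentation and density maps

Order of operations: nucleus-pixel classification → opening → hole
filling → Euclidean distance transform → sure foreground where
`dist > fg_frac · max(dist)` **within each connected component**
(default `fg_frac = 0.4`) → connected-component markers → watershed of
the inverted distance restricted to the nucleus mask.

Numerical choices worth noting:

* **Per-component thresholding.** A global `0.4 · max` erases small
  nuclei whenever a large one is present; per-component keeps the rule's
  spirit ("distance transform with an appropriate threshold") and is
  scale-free.
* **Ridge closing.** The sure-foreground is morphologically closed with
  disk r = 1: the discrete distance ridge of a thin 2:1 ellipse can dip
  below threshold mid-shape and fragment one nucleus into two markers.
* **Split geometry.** For two fused equal disks, the rule splits exactly
  when the neck half-width `sqrt(r² − (d/2)²)` falls below `0.4 r`,
  i.e. centre distance d > 1.833 r. The tests pin both sides of this
  boundary (split at 1.9 r, merged at 1.6 r).

Density map: per non-overlapping bin (16/32/64 px; the bin size must
divide the patch size), raw density = nucleus-pixel fraction, quantized
as `level = floor(raw · Ng)` clipped to `Ng − 1` with `Ng = 8`.
Quantization is absolute over [0, 1] — not per-patch rescaled — so maps
are comparable across patches and patients; a per-bin centroid-count
mode is available behind `mode="centroid"` for the alternative reading
of "estimated number of nuclei per region". Pixel-fraction is the
default because at 64-px bins nuclei routinely straddle bin borders.
Conservation (Σ raw · bin area = nucleus pixels) and scale-invariance of
the mean raw density are enforced by tests. Nucleus size/shape
categories (area cutoffs 100/300 px², eccentricity 0.8) are descriptive
metadata only.

## Haralick features

Four GLCMs per map at offset distance 1 — horizontal D1 (0, 1), vertical
D2 (1, 0), minor diagonal D3 (−1, 1), main diagonal D4 (1, 1) —
symmetrized (both pair orders counted) and normalized to unit mass.
The 13 classic statistics use: 0-based gray levels; log base 2 with
zero-probability terms skipped; `variance` = marginal variance of the
symmetric GLCM; `sum_variance` = variance of the (i+j) distribution
about the sum average; `correlation`, `IMC1`, `IMC2` defined as 0 for a
degenerate single-cell GLCM. The 14th statistic (maximal correlation
coefficient) is excluded — numerically unstable on 8×8 matrices and
unused by any downstream consumer. The implementation is checked to
1e−8 against an independent brute-force oracle and against
scikit-image's `graycoprops` for the shared statistics.

Slide aggregation: per (feature, direction, scale), five statistics over
retained patches — mean, median, sample variance (ddof 1), Fisher excess
kurtosis and bias-corrected skewness (both NaN with a warning below 4
patches) — named `{stat}_{feature}_{direction}`, 260 per scale. The
slide table is kept per-scale (S1/S2/S3 blocks), matching per-scale
reporting; the flat export suffixes the scale tag to keep names unique.

## Radiomics schema

The canonical 851-name schema is shape (14) + first-order (18) + GLCM
(24) + GLRLM (16) + GLSZM (16) + GLDM (14) + NGTDM (5) = 107 on the
original image, plus the six non-shape families (93) on each of 8
wavelet sub-bands (LLL…HHH): 107 + 744 = 851. Shape describes mask
geometry and is filter-invariant, hence original-only. The enumeration
is pinned by a golden file in the repo. Actual CT extraction (B-spline
1 mm³ resampling, an IBSI-compliant extractor) is upstream provenance,
deliberately not re-implemented; schema conformance of user tables is
advisory — synthetic cohorts use generic `f1..fK` names and proceed with
a warning. The gray-level discretization used upstream is carried in
provenance, never assumed.

## Association statistics

* z-score: per column, sample SD (ddof 1); zero-variance columns dropped
  with a warning.
* Spearman: Pearson on average ranks; p two-sided from the t
  approximation (df = n − 2); constant inputs → missing with warning.
* Redundancy filter (|ρ| > 0.9): iterate — take the currently largest
  |ρ| pair above threshold (lexicographic tie-break), eliminate the
  member with the higher mean absolute correlation against current
  survivors (tie: later name), recompute, stop when no pair exceeds the
  threshold. The iteration order is pinned purely for determinism; the
  post-condition (no retained pair above threshold) is swept by test.
  Applied per modality and, for pathomics, per scale.
* Endpoint correlations use observed OS/PFS months and **ignore
  censoring** — a deliberate caveat of this descriptive design, matching
  the Spearman-vs-months analysis it implements; it is not a survival
  model. Missing endpoints are handled pairwise-complete with per-feature
  n recorded. FDR is Benjamini–Hochberg at 0.05.
* KS: two-sample, two-sided, asymptotic p-value (the standard library
  default in this setting); exact-mode and censoring-exclusion variants
  are run-config options rather than assumptions. Note the feature-level
  correlation values entering the KS test are mutually dependent (they
  share patients), so its p-values are descriptive rather than exactly
  calibrated; the replicate experiment quantifies realised
  power/retention rates instead of trusting nominal levels.

## Clustering

Ward linkage on Euclidean distances over z-scored features — published
descriptive analyses of this kind rarely pin linkage or metric, so the
common default is used and recorded in the run config with alternatives
selectable — cut to exactly k = 2. Labels are canonical —
cluster 0 is the larger cluster, ties broken by the lexicographically
smallest patient id — and rows are sorted before linkage, so output is
independent of input row order. Summaries count observed PFS > 12 mo,
OS > 12 mo (censoring ignored, as above) and CD8 strictly above the
cohort median (computed over all patients with non-missing CD8);
percentages are rounded for display with exact fractions retained.
Clustering uses post-filter features by default (`cluster_on_filtered`).

## Problem sizes in the recovery experiments

Chosen once as realistic exercise sizes for each property:

* segmentation recovery: 200 tiles at the generator's default density
  range (512 px, rates from the latent model);
* cross-modal recovery: 200 patients, 2 tiles each, loadings ±0.8,
  noise SD 0.6; recovery is the correlation across features between the
  estimated Spearman vector (a density-linked slide feature vs every
  radiomics feature) and the planted `a_j / sqrt(a_j² + σ²)`. The
  loading *range* spreads the implied correlations so that this
  correlation is informative; a single common loading would make it
  degenerate (zero variance);
* KS power/calibration: 30 replicates of 200 patients × 120 features
  per modality, without images — the KS stage consumes correlation
  vectors, so tile synthesis adds nothing to what it tests;
* clustering: two 20-patient blobs, 10 SD apart, 5 features.

## Known limitations

* Nucleus segmentation has no shape priors; heavily fused nuclei
  (centre distance < 1.83 r) are a single label by construction.
* The synthetic radiomics table is a one-factor linear model — it cannot
  probe multi-factor redundancy structure among CT features.
* Endpoint statistics ignore censoring; with heavy censoring the
  Spearman-vs-months estimates are biased toward the censoring horizon.
* The 851-name schema pins one extractor convention; tables from other
  extractors validate with warnings, not errors.
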