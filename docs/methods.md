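# Methods

This note records the model, the numerical choices, and what the synthetic
test bed does and does not demonstrate.

## The measure

An image's complexity score is a linear combination of eleven objective
measures, each min-max normalized to [0, 1] over the stimulus set being
analysed:

    x_j = sum_k a_k x_kj,   a_k in [-1, 1],  k = 1..11.

Normalization is per dataset: the stored per-column (min, max) make the
transform invertible and reapplicable to new rows, but a weight vector
transferred across datasets is always applied to features normalized
*within* the evaluation dataset.  The bounded weight range exists because
both monotonicities occur among the measures (e.g. GLCM energy falls with
complexity while region count rises), and bounding the search space keeps
the multi-run average interpretable.

### The eleven measures

| # | measure | definition | notes |
|---|---------|-----------|-------|
| M1 | GLCM contrast | Σ p(i,j)(i−j)² | |
| M2 | GLCM correlation | Σ p(i,j)(i−μᵢ)(j−μⱼ)/(σᵢσⱼ) | undefined on constant images; mapped to 1.0 with a warning |
| M3 | GLCM energy | Σ p(i,j)² | |
| M4 | GLCM homogeneity | Σ p(i,j)/(1+\|i−j\|) | inverse difference moment, MATLAB-toolbox convention (not the squared-difference kernel) |
| M5 | frequency factor | r₉₉ / 0.5 | smallest radial frequency holding 99% of non-DC spectral energy, over Nyquist |
| M6 | edge density | Canny edge pixels / total | sigma 1, hysteresis 0.11/0.27 on [0,1] gradients |
| M7 | compression ratio | JPEG(Q=100) bytes / 3HW | 4:4:4 subsampling, baseline Huffman, pinned encoder |
| M8 | number of regions | mean-shift segment count | CIELUV, spatial bw 8 px, range bw 7, min region 20 px |
| M9 | colorfulness | √(σ²rg+σ²yb) + 0.3 √(μ²rg+μ²yb) | opponent axes rg = R−G, yb = (R+G)/2−B |
| M10 | number of colors | distinct 24-bit triplets | optional per-channel quantization knob |
| M11 | color harmony | area-weighted mean pairwise CH | two-colour model: chromatic + lightness + hue effects |

M1–M6 operate on the BT.601 luma image; GLCMs default to 8 levels at
offset (0, 1) with non-symmetric counts and linear intensity binning (the
common texture-toolbox defaults), all configurable in `FeatureConfig`.

Choices where conventions genuinely diverge:

* **M5** excludes the DC coefficient: the image mean carries no spatial
  structure, and including it would drag the factor toward 0 for bright
  flat images.  Radial frequency is the Euclidean norm of the per-axis
  FFT frequencies in cycles/pixel; coefficients are scanned in order of
  radius (stable sort) and the result clipped to [0, 1] since diagonal
  corners exceed Nyquist.
* **M8** uses EDISON-style local-mode filtering: each pixel's CIELUV value
  iteratively moves to the mean of the window pixels (disk radius 8)
  currently within range bandwidth 7, for up to 5 iterations; regions are
  4-connected components whose filtered colours differ by less than the
  range bandwidth, and regions under 20 px are merged into their most
  similar neighbour.  Images larger than 256 px on a side are downscaled
  with nearest-neighbour resampling — interpolation would paint
  transition colours along sharp boundaries that surface as spurious
  regions.
* **M11** needs an image-level aggregation of a pairwise colour-harmony
  model.  The image is quantized to 16 levels per channel, the most
  frequent colours with at least 1% area (up to 8) are taken as dominant,
  converted to CIELAB (sRGB/D65), and every unordered pair scored; the
  image score is the mean weighted by the product of the pair's area
  fractions.  A single dominant colour scores its self-pair.
* **M7**'s ratio can exceed 1 on tiny or noise-like images (header
  overhead); this is expected and left unclipped.

## Subjective score processing

Raw ratings r_ij on the [0, 100] slider are standardized per subject
(z_ij = (r_ij − mean_i)/sd_i, sample SD), cleaned per image by dropping
z-scores outside mean ± 2·SD across subjects, and averaged into mean
scores y_j.  The cleaning is a single pass — image statistics are not
recomputed after drops — which makes it idempotent.  The interval is read
as *half-width* 2 SD; the stricter total-width-2-SD reading (± 1 SD) is
available as `half_width_sd=1.0`.  Sample (n−1) SDs are used throughout.
Missing cells are skipped in all sums, and a warning fires if more than
10% of cells are dropped.  The whole chain is exactly invariant to a
positive affine rescaling of any single subject's ratings.

## Fitting

The fitness of a weight vector is the Pearson correlation between the
calibrated score f(x) and y, with the 5-parameter monotone logistic

    f(x) = b1 (1/2 − 1/(1 + exp(b2 (x − b3)))) + b4 x + b5

re-fitted by least squares for every candidate.  Numerical scheme
(variable projection): for fixed (b2, b3) the model is linear in
(b1, b4, b5) and solved from the normal equations; (b2, b3) are refined
by a deterministic Nelder-Mead from the start b2 = 1/SD(x),
b3 = median(x).  x is standardized internally and the parameters mapped
back, so the fitness is invariant to positive affine transforms of x to
machine precision — equivalently, weight vectors matter only up to scale.
Two guards keep the search well-posed: the SSE is evaluated from
residuals (the moment identity cancels catastrophically when the sigmoid
column is nearly collinear with the linear term), and |b2| is clamped to
at least 0.5 on the standardized scale (a flatter sigmoid spans the same
model space as the explicit linear term, with exploding coefficients).
On any failure the fit degrades to a plain linear map with a warning.

The optimizer is a hand-rolled global-best PSO: default 40 particles, 200
iterations, inertia 0.7298, cognitive = social = 1.4962 (the standard
constriction-equivalent setting), velocities clamped to half the search
range, positions clamped to [−1, 1].  Fitness ties resolve to the lowest
particle index.  The protocol repeats the optimization over independent
runs (default 1000; run r uses seed `base + r`) and reports the average
weight vector and the mean/SD/min/max of per-run best fitness.

Because the calibration absorbs *any* affine map — including sign flips —
+A and −A have identical fitness, and raw runs land on either sign at
random.  Each run's best vector is therefore oriented so the raw combined
score correlates positively with y before aggregation; without this the
multi-run average would cancel across mirrored solutions.

Shipped presets `LC_RS1` (real scenes) and `LC_TXT1` (textures) are fixed
weight vectors fitted with this protocol on their respective stimulus
sets; their printed performance applies to those sets, not to arbitrary
images.

## Synthetic test bed

`gen_study` plants the exact statistical structure the fitter assumes:
features i.i.d. uniform on [0, 1], scores a monotone logistic link of the
planted linear combination (centred at the median LC, slope 2/SD(LC))
plus Gaussian noise of SD 0.05 by default — a noise level that leaves the
planted direction clearly identifiable at N = 50, matching the scale of a
49–58 image stimulus set.  `gen_ratings` re-expands scores to the raw
slider scale with per-subject gain (SD 0.1), bias (SD 5 points), rating
noise (SD 0.3 on the standardized scale) and 2% wild outlier cells — the
contamination pattern the cleaning step exists for.  `gen_image` renders
axis-aligned mosaic tiles with optional jitter and pixel noise, giving
controllable region, colour and frequency content.

What passing these tests shows: the estimator recovers planted weight
directions (median cosine ≥ 0.9 at N = 50, noise 0.05), the rating chain
recovers planted difficulty ranks (Spearman ≥ 0.95 at S = 20, N = 49),
and the feature extractors satisfy their closed-form identities and
brute-force oracles.  What it does not show: real photographs are not
i.i.d. uniform in feature space (measures are mutually correlated), human
rating noise is not Gaussian, and the measures' perceptual relevance
cannot be established synthetically — that requires real stimulus sets
with human scores.

## Problem sizes

Tests and the acceptance script run the protocol at desk scale: swarms of
10–30 particles, 15–60 iterations, 1–20 runs, studies of 30–200 images.
The defaults in `PsoConfig` (40 × 200 × 1000) reproduce the full
protocol when compute time is no concern; fitness typically saturates
well before 200 iterations on N ≈ 50 problems.

## Known limitations

* Exact extractor settings used to produce any particular published
  feature table (GLCM offsets, Canny thresholds, mean-shift bandwidths,
  JPEG encoder dialect, colour-count quantization) vary between
  implementations; recomputed feature values should be expected to agree
  in rank, not digit-for-digit.  The correlation machinery is insensitive
  to monotone re-parametrizations of individual measures.
* The mean-shift filter is the fixed-window local-mode variant; region
  counts can differ slightly from moving-window implementations on
  gradient-heavy images.
* The study-table reader accepts .xlsx and .csv; legacy .xls workbooks
  need converting first.
* The logistic calibration assumes a monotone objective-subjective
  relationship; severely non-monotone measures yield near-zero fitness
  rather than an error.
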