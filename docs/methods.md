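# Methods

This note documents the models, numerical choices and assumptions behind
`hsilesion`: a pipeline that takes hyperspectral skin-lesion cubes (or
synthetic phantoms standing in for them) through reflectance calibration,
denoising, tissue-index computation, radiomic feature extraction,
minimum-redundancy maximum-relevance (mRMR) feature selection, and
three fixed classification pipelines evaluated by repeated stratified
cross-validation.

## The analysis problem

Head-and-neck skin carcinomas (BCC/SCC) present three clinically distinct
regions: the macroscopic tumor, a peritumoral zone of visually abnormal
skin, and surrounding healthy skin. A hyperspectral camera (400–1000 nm,
~7 nm sampling, 512×512 pixels) records a reflectance spectrum per pixel.
Instead of classifying raw spectra, the pipeline reduces each cube to
twelve *tissue-index images* — scalar maps estimating blood content,
melanin, oxygenation at two depths, water and perfusion — plus an RGB
rendering, then asks whether 2D texture radiomics of those maps separates
the three region classes.

Because the clinical cohort is not public, a synthetic-data module
generates phantoms with the geometry and printed region statistics of the
study, and the whole pipeline is exercised end-to-end on those phantoms.
Every performance number this package reports is therefore a statement
about the phantoms, not about patients.

## Reflectance calibration and QA

Raw counts are converted per band to reflectance
`R = (I_raw − I_dark) / (I_white − I_dark)` using white-standard and
dark-current frames (full-cube or line-scan references; line references
are broadcast across rows). Degenerate denominators become NaN and are
counted. QA reports the fraction of skin reflectances ≥ 1 (must be rare;
default pass threshold 1%) and the fraction inside the well-exposed
0.3–0.7 window. One contract interaction is worth noting: reference
frames with white ≤ dark on more than 1% of pixels are rejected at
construction, so the normalization-time "many degenerate pixels" warning
is defensive and unreachable through the public API.

## MNF denoising

The minimum noise fraction transform estimates a noise covariance from
horizontal first differences of neighboring pixels, `Σ_N =
cov(x[i,j]−x[i,j+1])/2` (direction configurable), whitens the data by
`Σ_N^{-1/2}`, performs PCA in the whitened space, truncates to the
leading components and back-projects. Components are kept while their
noise-whitened variance exceeds 1 (i.e. variance above the noise floor);
an integer override is available. Singular noise covariances are
ridge-regularized with `ε = 1e−8·trace/bands`. Keeping all components
reproduces the input to numerical precision. The estimator assumes the
signal is spatially smoother than the noise; on images whose true signal
varies pixel-to-pixel the "noise" estimate absorbs signal gradients and
denoising gains vanish (this is inherent to neighbor-difference MNF, and
the test phantoms therefore use smooth abundance maps).

## Skin segmentation (SAM)

Per-pixel spectral angle `arccos(⟨a,b⟩/‖a‖‖b‖)` to a reference spectrum
taken from a manually chosen skin pixel. The angle is illumination-scale
invariant. Default threshold: **0.25 rad**. On calibrated phantoms the
within-skin angle spread to a single healthy-pixel reference reaches
~0.15–0.25 rad (tumor spectra differ most), while the skin-to-background
gap exceeds 0.5 rad, so 0.25 recovers ≥99% of skin pixels with margin on
both sides. An optional largest-connected-component filter is available.

## RGB rendering

`XYZ = Σ_λ R(λ)·S_D65(λ)·x̄ȳz̄(λ)·Δλ`, normalized so a perfect reflector
has Y = 1, converted to linear sRGB (D65), gamma-encoded and clipped.
The CIE 1931 2° color-matching functions use the published multi-lobe
piecewise-Gaussian analytic fit; D65 is a 10 nm table, interpolated.
Because rendering is white-point normalized, residual table error cancels
for near-neutral scenes; only qualitative color behavior is asserted.

## Tissue indices

All twelve indices are computed from absorbance `A(λ) = −log10 R(λ)`,
with `R` at each required wavelength taken as the mean over a ±3.5 nm
window (one camera band; nearest-band mode available). Pixels with
non-positive reflectance at a required band become NaN.

The exact equations behind the study's index set are not available in the
source text, so the registry transcribes each index from its standard
literature form; the specific wavelength sets are package choices and are
recorded in the per-index provenance:

| symbol | formula (A in absorbance units) |
|---|---|
| E_Daw | `100·[A560 + 1.5(A545+A575) − 2(A510+A610)]` |
| E_c_Daw | `E_Daw − 1.5·M_Daw` |
| E_Diff | `100·(A560 − A650)` |
| M_Daw | `100·(A650 − A700)` |
| oxy_H | `100·(A542+A577)/(A542+A577+2·A556)` |
| oxy_I | `100·A850/(A760+A850)` |
| E_Wag | `100·[mean(A545,A555,A565,A575) − A650]` |
| M_Wag | `100·(A660 − A780)` |
| oxy_T | `100·(A580+A850)/(A580+A850+A560+A760)` |
| TWI | `100·(A970 − A860)` |
| THI | `100·[mean(A544,A560,A576) − A690]` |
| NTP | `100·(A800 − A690)` |

The erythema/melanin/water/hemoglobin/perfusion forms are weighted
absorbance differences with zero weight sum, hence invariant to a global
positive gain on reflectance (property-tested). The three oxygenation
ratios are not gain-invariant. Under the phantom forward model, the four
indices with published region statistics (E_Daw, oxy_I, oxy_H, M_Daw)
reproduce the tumor > peritumor > healthy ordering; TWI and NTP do not
order monotonically under the coarse chromophore shapes (their baseline
bands carry competing blood/melanin signal), and no ordering is published
for them, so none is asserted.

## Synthetic phantoms

**Geometry.** Tumor: filled disc. Peritumor: annulus. Healthy skin: a
centered square frame with the peritumor disc as central void. Solving
the published pixel ratios healthy:tumor = 40:1 and healthy:peritumor =
11:1 gives `r_peri = r_tumor·√(51/11)` and `side = r_tumor·√(491π/11)`;
the defaults (r_t = 40 px on a 512×512 frame, scaled proportionally for
other sizes) land within ~0.5% of both ratios after rasterization.

**Index-space phantoms** draw each index image directly: per region, a
Gaussian random field (FFT-filtered white noise, Gaussian transfer
function) with region correlation length, scaled to the configured
(mean, sd). Published calibration: Dawson erythema 98.97 ± 21.43 /
70.58 ± 13.32 / 67.87 ± 20.70 (tumor/peritumor/healthy), Ishimaru
oxygenation 70.16 ± 2.12 / 68.41 ± 2.24 / 65.34 ± 4.02, Dawson melanin
5.92 ± 0.94 (tumor) and 4.46 ± 0.91 (healthy). The peritumor melanin
mean (5.20) and all parameters of the other nine indices are package
assumptions, flagged `assumed` in the phantom manifest. Correlation
lengths default to 3 px (tumor), 5 px (peritumor), 8 px (healthy),
encoding the greater spatial non-uniformity of healthy skin texture.
Background pixels are NaN and excluded from all statistics. A 13th
grayscale "RGB" channel with its own per-region parameters stands in for
the color photograph, since index phantoms have no spectrum to render.

Sampling note: a correlated field has effective sample size ≈
`N/(4πℓ²)` for correlation length ℓ, so region-mean recovery tests use
`SE = sd·√(4πℓ²/N)` rather than the iid standard error.

**Spectral phantoms** synthesize per-pixel reflectance by a Beer–Lambert
forward model `R(λ) = 0.9·exp(−ℓ·Σ c_i μ_a,i(λ))` over four chromophores
(oxy-/deoxy-hemoglobin, melanin, water) with coarse analytic absorption
shapes (Gaussian Soret/Q bands, 760 nm deoxy shoulder, ~800 nm isosbestic
crossover, melanin power law, 970 nm water band). These shapes are
qualitative: they reproduce orderings and band structure, not calibrated
optical densities. Raw cubes are `dark + R·(white−dark) + noise`, so
Eq.-style normalization recovers `R` exactly at zero noise. Default
chromophore fractions (blood 0.025/0.017/0.012, saturation
0.75/0.68/0.62, melanin 0.040/0.035/0.030, water 0.75/0.70/0.65 for
tumor/peritumor/healthy) keep skin reflectance inside (0,1) and mostly in
the 0.3–0.7 QA window.

**Study replicas** contain n lesions (default 24 → 72 ROIs, exactly
balanced across the three classes). Per lesion, every (index, region)
mean is jittered with sd = 25% of that index's between-region contrast,
emulating patient-to-patient variability around pooled statistics.

What the phantoms do *not* emulate: real lesion shapes and boundary
irregularity, specular artifacts, illumination non-uniformity, camera
spectral response, inter-index correlations within a pixel (each index
field is drawn independently), and any real relationship between texture
and pathology. Passing tests demonstrate pipeline correctness and
internal consistency, not clinical performance.

## Radiomics (93 features)

Features follow the reference-standard definitions used in quantitative
radiomics: 18 first-order features plus five texture-matrix families
(24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM). The shape class is
excluded by design — region shapes are fixed by construction (disc,
annulus, frame) and would leak the class label.

Choices the reference standard leaves open, fixed here as defaults:

- gray-level discretization: fixed bin count 32 per ROI
  (`level = ceil(N_g(x−min)/(max−max))` clamped to [1, N_g]); index images
  have heterogeneous ranges, making fixed bin width unportable;
- texture matrices: distance 1, four 2D directions (0°/45°/90°/135°),
  per-direction features averaged; GLCM symmetric;
- GLSZM zones: 8-connectivity; NGTDM: 8-neighborhood, pixels without any
  in-mask neighbor excluded; GLDM: dependence threshold α = 0 with the
  center pixel counted, so dependence sizes start at 1;
- degenerate fallbacks (never NaN): correlation-type features → 1 for a
  single gray level, NGTDM coarseness saturates at 1e6, everything else
  → 0;
- RGB images are reduced to Rec. 709 luminance before extraction.

The extractor is validated feature-by-feature against an independent
brute-force implementation (plain loops, explicit flood fill) on ≥100
random small ROIs at 1e−8 relative tolerance.

## Feature selection

Stage 1 runs mRMR within each channel (each tissue index, and RGB),
keeping 7 features per channel; stage 2 runs mRMR on the pooled
survivors (84 columns for the index-only scenario, 91 with RGB) down to
a final 7. The mRMR variant is FCD: relevance = one-way ANOVA
F statistic, redundancy = mean |Pearson r| with the selected set,
combined by difference; greedy, deterministic, with lexicographic
tie-breaks. Two numerical guards matter:

- relevance is max-normalized to [0, 1] so the two terms are
  commensurate (raw F values in the hundreds would reduce FCD to a pure
  relevance ranking); infinite F (perfect separators) maps to 10× the
  largest finite value;
- candidates with |r| ≥ 0.95 to an already-selected feature are deferred
  until nothing else remains: an exact duplicate scores ~rel−1 ≈ 0 under
  the difference rule, which still beats the slightly negative scores of
  independent noise features.

A mutual-information variant (equal-frequency discretization, 8 bins) is
available behind `method="mi"`.

Because three-class relevance is dominated by the tumor-vs-healthy
contrast, a final augmentation step re-runs mRMR on the tumor/peritumor
rows only and swaps its top features into the final set (replacing the
lowest-ranked non-forced features) until at least two tumor-vs-peritumor
discriminators are present; the set size stays 7.

## Classifiers and evaluation

Three fixed pipelines, reflecting an AutoML search that is itself out of
scope (only its end products are implemented):

- **Scenario I** (RGB features): gradient boosting, max depth 8, max
  feature subset 0.2, min samples/leaf 4, min samples/split 5;
- **Scenario II** (index features): extremely randomized trees,
  bootstrap, max features 0.25, min samples leaf 5, min samples split
  20, fixed random state 111;
- **Scenario III** (combined): a stacking transformer that appends an
  SGD linear classifier's class probabilities and predicted class index
  to the features (SGD: alpha 0.0, eta0 0.01, no intercept, l1 ratio
  0.0, inverse-scaling learning rate, modified-Huber loss, elastic-net
  penalty, power_t 100.0), then a zero-count feature constructor
  (per-row counts of zero and non-zero entries), then a linear SVC
  (dual false, L1 penalty, tol 1e−3). This pipeline exposes no
  probability outputs, so ROC/AUC is refused for it by design.

The scenario III SGD settings are kept verbatim even though alpha = 0
disables regularization and power_t = 100 collapses the learning rate
after the first update; a warning is logged at construction.

Evaluation: repeated stratified 8-fold CV with 30 repetitions. Each
repetition's out-of-fold predictions are pooled into one vector before
computing that repetition's metrics, giving 30-point traces and
mean ± SD for accuracy, macro precision/recall/F1 and balanced accuracy
(balanced accuracy = macro recall by definition; with exactly balanced
classes macro and weighted averaging coincide in expectation). One-vs-
rest ROC uses stratified 4-fold CV with per-class AUC averaged over the
folds. Feature importances come from a 200-tree extremely randomized
ensemble (impurity-based, summing to 1); note that column permutation
equivariance of such importances holds only in expectation, since
threshold sampling consumes the RNG in column order.

The default orchestration holds out a lesion-grouped stratified 25% test
split (no lesion contributes ROIs to both sides; because each lesion has
one ROI per class, the grouped split is automatically stratified), runs
the repeated CV on the training portion and reports held-out metrics
alongside; `cv_on_full_table=True` evaluates on the full table instead.

## Problem sizes

Default replica for end-to-end runs and tests: 24 lesions on 128×128
frames (the camera-scale 512×512 geometry is used where ≥10⁴-pixel
regions are required, e.g. calibration recovery). These sizes keep a
complete scenario run with feature extraction, two-stage selection and
8×30 repeated CV around a minute on one CPU while preserving the study's
region pixel ratios and class structure.

## Known limitations

- Index wavelength sets are literature-style reconstructions, not the
  study's exact equations; absolute index values in spectral mode are
  not comparable to published figures (index-space phantoms are, by
  construction).
- The chromophore library is qualitative; no radiative transfer, no
  depth resolution, no scattering model.
- Phantom classes are separable nearly by construction; CV accuracies
  near 1.0 on default replicas say nothing about clinical data.
- MNF assumes noise is spatially rougher than signal.
- 2D-only radiomics; no wavelet/LoG filtered variants.
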