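# Methods

`dectexture` implements a quantitative dual-energy CT (DECT) analysis of
thyroid nodules on virtual monochromatic images (VMIs): a 41-feature texture
panel per nodule per energy, iodine-concentration and spectral-slope
quantification, and a benign-vs-malignant group comparison with ROC
analysis.  Because no patient data accompany the study design this package
targets, a synthetic phantom cohort is a first-class component: it defines
controlled ground truth against which every downstream stage is validated.

## Phantom model

Each nodule is an axis-aligned ellipsoid (in-plane semi-axes drawn uniformly
from 5.5–9.0 mm, through-plane semi-axis 4.5 mm) embedded in a small volume
of 3 mm axial slices (default 5 slices of 64×64 voxels at 0.6 mm in-plane).
The attenuation inside the nodule at VMI energy E is

    HU(E) = base(E) + c · k(E) + t(x) + ε(E),

with `c` the nodule's true iodine concentration (mg/mL), `k(E)` the iodine
enhancement in HU per mg/mL (a strictly decreasing placeholder
`50·(40/E)^1.6`, ≈50 at 40 keV to ≈4 at 190 keV — only monotone decay and
linearity in `c` are contractual, not scanner physics), `t(x)` a zero-mean
Gaussian texture field shared across energies, and `ε(E)` white noise whose
SD falls with energy (`5 + 1000/E` HU), as monochromatic image noise does.
The background `base(E) = 1030 + 3200/E` places ROI means on the offset
CT-number scale (≈1070–1110) on which published thyroid texture values are
reported.

The texture field is white noise smoothed by an isotropic Gaussian kernel
whose width (in voxels, per axis) encodes the correlation length in mm, then
mean-subtracted and rescaled so its empirical SD equals the configured
amplitude exactly.  This is the simplest model in which heterogeneity
amplitude and length scale are independently controllable.  Malignant
nodules default to a shorter correlation length (1.5 vs 4.0 mm) and larger
amplitude (30 vs 15 HU), reflecting the greater spatial heterogeneity of
malignant tissue; benign/malignant mean iodine defaults are 0.54/0.437 mg/mL
with a within-class SD of 0.37 mg/mL borrowed from ex vivo thyroid
dispersions — illustrative values, since in vivo within-class variance is
not well characterized.  Iodine samples are deliberately not truncated at
zero: decomposition maps genuinely contain negative values, and truncation
would bias class means away from their configured targets.  The iodine map
adds voxel noise (SD 0.05 mg/mL) to the per-nodule truth.

Cohort generation is a pure function of `(PhantomConfig, rng_seed)`.

What the phantom does **not** emulate: beam hardening, cross-scatter,
calcifications and cysts (masks are solid by construction), inter-reader
segmentation variability, and any projection-domain physics.  Passing the
recovery tests therefore demonstrates that the pipeline's estimators are
correct and well calibrated under the stated model — not that the published
patient-level discriminative performance transfers to real scans.

## ROI conventions

One binary mask per nodule is shared across all energies (VMIs from a single
acquisition are natively coregistered; no per-energy re-segmentation).
Voxel indexing is 0-based, positions are voxel centers, and the in-plane
diameter is the maximum center-to-center distance within any axial slice
(exact pairwise distances; convex-hull reduction above 400 points per
slice).  Nodules whose solid component is below 10 mm — the minimum
fine-needle-aspiration size in ACR TI-RADS — are dropped and logged.
Artifact-affected slices can be excluded (`exclude_slices`); excluding every
slice is an error.

## Texture features

41 features in five families, computed per axial slice on the masked region
and averaged (unweighted) across usable slices (≥ 9 voxels and at least one
voxel with full 3×3 in-mask support):

* **histogram (12)** — mean, median, SD, variance, skewness, kurtosis,
  energy, entropy (256 bins over the ROI range), min, max, range, IQR; on
  raw HU.
* **GLCM (5)** — contrast, correlation, energy (= Σp²), homogeneity
  (Σ p/(1+(i−j)²)), entropy (log₂); distance 1, four directions, pairs
  restricted to the mask, symmetrized and normalized per direction, averaged
  over directions.
* **GLRL (11)** — SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE,
  LRHGE over maximal constant-level runs (broken at mask boundaries), four
  directions averaged; gray levels indexed from 1 in the emphasis weights.
* **GLGM (4)** — mean (MGR), variance (VGR), skewness, kurtosis of
  central-difference gradient magnitudes at interior voxels (all four
  4-neighbours in-mask), spacing-corrected.
* **Laws (9)** — mean absolute response of the nine 3×3 outer-product
  kernels of L3=[1,2,1], E3=[−1,0,1], S3=[−1,2,−1] on ROI-mean-subtracted
  intensities, over voxels with full 3×3 in-mask support.  The 3×3 basis is
  chosen because exactly nine masks arise from the three 1D kernels.

GLCM and GLRL operate on intensities quantized to 64 levels over the
per-slice ROI min–max range (configurable; 64 is a common radiomics
default).  Skewness/kurtosis use population (biased) moments, kurtosis
non-excess.  Degenerate slices take defined limits instead of NaN: constant
ROIs give GLCM contrast 0, energy 1, entropy 0, homogeneity 1, and
correlation is defined as 0 when a marginal variance vanishes; zero-variance
gradient distributions give skewness/kurtosis 0.

All four matrix/gradient/kernel families are verified against independent
brute-force enumeration oracles (nested-loop implementations kept in the
test suite) on random small images, to 10⁻⁹ relative agreement, and GLCM is
additionally cross-checked against scikit-image on unmasked rectangles.

A note on quantization and heterogeneity: with ROI min–max quantization the
GLCM is invariant to affine intensity changes, so a pure gain in texture
amplitude does not raise quantized contrast — relative to fixed image noise
it can even lower it, because white noise carries more contrast per unit
range than a smooth field.  The monotone-heterogeneity property (larger
amplitude ⇒ larger contrast) therefore holds, and is tested, under a fixed
quantization window; the mean gradient (raw HU) is monotone in amplitude
under either convention.

## Spectral quantities

Iodine concentration is the unweighted ROI mean of the iodine map.  The
attenuation slope is the OLS slope of ROI mean HU against energy over the
40–190 keV sweep (10 keV steps by default); with two energies this reduces
to the difference quotient.  Because published "slope" values are positive
while enhancing tissue has falling HU curves, the reported statistic is the
magnitude (the signed value is retained).  "Normalized slope" is not
defined precisely in the clinical literature this targets; both |slope| and
|slope| / |HU(reference)| (reference 190 keV by default) are reported rather
than asserting one reading.

## Statistics

For every feature × energy (and for iodine content and slope): the two
classes' variances are compared with the two-sided F-ratio test at α = 0.05
(the classical SAS-style gate behind "pooled or Satterthwaite" reporting;
Levene-style alternatives were considered but the F-gate reproduces the
published P values — see below); the gate selects the pooled t-test
(df = n₁+n₂−2) or the Satterthwaite/Welch test (Welch–Satterthwaite df).
P values are raw and two-sided; Benjamini–Hochberg adjustment is available
but off by default.  Degenerate inputs: both variances zero with equal
means gives t = 0, p = 1; with unequal means, p → 0.

ROC analysis uses the midrank Mann–Whitney AUC, with orientation folded so
AUC ≥ 0.5 and recorded as the inequality direction that flags malignancy.
The operating cut-off maximizes Youden's J over observed values, ties broken
toward higher specificity and then toward the more extreme threshold; the
decision boundary is inclusive on the malignant side.  Sensitivity is
defined on the malignant class and specificity on the benign class,
uniformly — published tables in this area sometimes swap the class bases
between rows, which this implementation does not reproduce.

The per-group sample-size estimate uses the standard normal-approximation
formula n = ⌈2σ²(z₁₋α/₂+z₁₋β)²/δ²⌉, floored at 2.

Against the published diagnostic-performance table, the five rows whose
P values are recomputable from printed (n, mean, SD) all reproduce to three
decimals under the F-gate (0.014, 0.034, 0.038, 0.028, 0.052).  One further
row (MGR at 40 keV, printed 0.035) matches the Satterthwaite P (0.0349)
although the F-gate at α = 0.05 selects pooled (0.0507); the original
variance test is unknown, so the package documents the discrepancy and the
`both_methods` option reports the two P values side by side rather than
matching that cell.

## Model/results interface

The cohort-level comparison follows the estimator idiom of statistical
modelling packages: `CohortComparison(feature_table, spectral_table)` is the
model, `fit()` returns a `CohortComparisonResults` whose `table` holds one
row per feature per energy (group summaries, gate method, t, df, P, cut-off,
sensitivity/specificity in %, AUC to 3 decimals) plus the two spectral rows,
with `summary()` rendering a readable report and `to_csv()` the
machine-readable one.  The earlier pipeline stages (phantom, I/O, texture,
spectral) are deterministic transforms, not fitted models, and are exposed
as plain functions.

## Problem sizes and numerical choices

Validation cohorts use 3-slice 40×40 grids at 0.7 mm so that nodules of
11–16 mm diameter pass the size criterion while each ROI still spans several
hundred voxels; calibration uses 2,000 null replicates at the study's group
sizes (14/20); oracle equivalence uses 100 random images ≤ 6×6 with ≤ 4
gray levels; recovery experiments use 20 seeded replicates.  All randomness
flows through `numpy.random.default_rng` seeds; cohort generation, feature
extraction and reporting are single-threaded and bit-reproducible given the
seed.

## Known limitations

* Feature magnitudes are not calibrated to any particular scanner or to the
  published table's scales (e.g. printed GLGM skewness magnitudes are not
  standardized-moment values); only the statistical protocol applied to the
  printed summaries, and internal consistency on phantoms, are validated.
* The exact identities of the published 12 histogram and 5 GLCM features are
  not public; the canonical sets implemented here match the family counts
  and include every feature the published table names.
* 2D per-slice analysis only; no wavelet/fractal features, no classifiers,
  no AUC confidence intervals.
* The phantom's iodine dispersion and texture parameters are illustrative;
  recovered AUCs on the phantom say nothing about clinical AUCs.
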