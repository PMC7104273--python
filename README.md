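# dectexture

Quantitative dual-energy CT (DECT) analysis of thyroid nodules on virtual
monochromatic images (VMIs).  The package is aimed at radiomics researchers
who want a tested, reproducible implementation of a common clinical-study
protocol: characterize each nodule by (1) its iodine concentration and
spectral attenuation-curve slope from DECT material decomposition, and
(2) a 41-feature texture panel on VMIs at 40/60/80 keV, then compare benign
and malignant groups feature by feature with variance-gated t-tests and ROC
analysis.

Because studies of this kind rarely release images, `dectexture` ships a
synthetic DECT phantom generator as a first-class module: it produces
coregistered per-energy volumes, an iodine map and ROI masks for two nodule
classes that differ in iodine content and spatial heterogeneity, with known
ground truth, so the entire pipeline is testable end to end.

## The core quantities

Per nodule, with ROI mask M shared across energies:

* **Iodine content** — mean of the iodine map over M (mg/mL).
* **Spectral slope** — OLS slope of mean ROI HU against energy over the
  40–190 keV sweep; reported as a magnitude, with a normalized variant
  |slope|/|HU(190 keV)|.
* **Texture panel (41 features per energy)** — 12 histogram, 5 gray-level
  co-occurrence (GLCM: contrast, correlation, energy, homogeneity, entropy),
  11 run-length (GLRL: SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE,
  LRLGE, LRHGE), 4 gradient (GLGM: MGR, VGR, skewness, kurtosis) and
  9 Laws (3×3 L3/E3/S3 outer-product kernels), computed per slice within the
  mask and averaged across slices.

Per feature × energy the group comparison reports (n, mean, SD) per class;
an F-ratio variance gate choosing the pooled (equal-variance,
df = n₁+n₂−2) or Satterthwaite (Welch) t-test; the raw two-sided P; and the
empirical ROC AUC with the Youden-optimal cut-off, sensitivity and
specificity.  See `docs/methods.md` for definitions and conventions.

## Worked example

```python
from dectexture import PhantomConfig, generate_cohort, CohortComparison
from dectexture.pipeline import extract_features_cohort, spectral_cohort

cfg = PhantomConfig(n_benign=14, n_malignant=20, rng_seed=7,
                    image_shape=(3, 48, 48), voxel_size_mm=(3.0, 0.6, 0.6))
cohort = generate_cohort(cfg)
features = extract_features_cohort(cohort, energies=(40.0, 60.0, 80.0))
spectral = spectral_cohort(cohort)
results = CohortComparison(features, spectral).fit()
print(results.table[results.table.feature.isin(
    ["histogram.mean", "glgm.MGR", "spectral.iodine_content"])]
    [["feature", "energy_keV", "benign_mean", "malignant_mean",
      "method", "p", "cutoff_direction", "cutoff", "auc"]])
```

yields (125 rows total: 41 features × 3 energies + iodine and slope):

```
                feature  energy_keV  benign_mean  malignant_mean        method            p cutoff_direction      cutoff   auc
         histogram.mean        40.0  1138.086133     1127.107258        pooled 1.728902e-01                < 1143.769477 0.650
               glgm.MGR        40.0    44.011495       46.957796        pooled 7.123968e-07                >   45.661073 0.968
         histogram.mean        60.0  1099.829984     1091.758830        pooled 1.394152e-01                < 1094.650053 0.646
               glgm.MGR        60.0    32.560619       35.997472        pooled 1.886628e-08                >   34.607660 0.961
         histogram.mean        80.0  1082.372375     1074.913737        pooled 9.271305e-02                < 1080.401785 0.679
               glgm.MGR        80.0    26.103160       30.594367 satterthwaite 6.407567e-14                >   28.719075 1.000
spectral.iodine_content         NaN     0.476263        0.369247        pooled 4.152028e-01                <    0.586717 0.575
```

Read: on this synthetic cohort the iodine difference between classes is too
small relative to its dispersion to reach significance (P = 0.42, AUC 0.58),
while the mean gradient (GLGM MGR) — which responds to the malignant class's
shorter-range, larger-amplitude heterogeneity — separates the groups
decisively at every energy, with malignant nodules above the cut-off
(orientation `>`).  Histogram mean trends lower in malignant nodules
(orientation `<`) without reaching significance at these settings.

The same pipeline runs from the shell on written NIfTI cohorts:

```
dectexture all --out run1 --seed 7 --n-benign 14 --n-malignant 20
```

producing `manifest.csv`, per-nodule NIfTI volumes, `features.csv`,
`spectral.csv` and `report.csv` in `run1/`; rerunning with the same seed
reproduces every table bit-identically.

The statistics layer also works directly from published summary statistics:

```python
from dectexture import two_sample_t_from_summary
r = two_sample_t_from_summary(1086.7, 18.6, 14, 1071.9, 9.5, 20)
print(r.method, round(r.p_two_sided, 3))   # satterthwaite 0.014
```

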