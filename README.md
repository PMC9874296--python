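# vaximg

Multimodal quantification of the local immune response to intramuscular
vaccination, for preclinical imaging groups comparing vaccine platforms
(e.g. an adjuvanted protein vs. an LNP-formulated self-amplifying mRNA) in
rodents. The package turns three kinds of raw measurements — multi-echo MR
volumes, static-frame FDG-PET volumes, and imaging-mass-cytometry (IMC)
single-cell tables from the draining lymph node — into the quantitative
endpoints used to compare treatment groups over time, and ships a
synthetic-data generator with full ground truth so every stage is testable
without animal data.

## What it computes

**MRI relaxometry and volumetry** (`vaximg.mri`). Per-voxel T2/M0 maps from
a multi-slice multi-echo acquisition under the mono-exponential model
S(TE) = M0·exp(−TE/T2), fitted by log-linear OLS (or nonlinear least
squares). Signal-enhancement volume: voxels of a search region strictly
above mean + k·SD (default k = 2) of a contralateral control region, times
the voxel volume. ROI statistics (mean T2, volume) for lymph nodes.

**PET quantification** (`vaximg.pet`). Decay correction to injection time
(×2^(Δt/T½), T½ = 109.77 min for ¹⁸F), conversion to percent injected dose
per gram (%ID/g = 100·C/dose, density 1 g/mL), baseline-threshold
enhancement volumetry, and total uptake (glycolytic burden) = mean %ID/g ×
enhancement volume.

**Radiomics** (`vaximg.radiomics`). First-order energy (Σ intensity²),
first-order interquartile range, and the Gray Level Dependence Matrix
Dependence Non-Uniformity, DNU = Σ_d(Σ_g P(g,d))²/N with equal-width
discretisation over the in-ROI range and 26-connected neighbourhoods; plus
Pearson correlation-threshold feature selection.

**IMC single-cell phenotyping** (`vaximg.imc`). Per-channel z-scoring,
two-component Gaussian-mixture positivity gating (posterior > 0.5 for the
higher-mean component), K-means clustering on z-scores, rule-based
phenotype assignment from canonical markers (e.g. follicular dendritic
cells are CD21+CD20−), and per-sample cell-type ratios.

**Spatial metrics** (`vaximg.spatial`). For phenotypes A and B within a
sample mosaic: the mean number of B cells within 15 µm of each A cell
(boundary inclusive) and the median nearest-neighbour distance from A
cells to B cells.

**Statistics** (`vaximg.stats`). Per-subject trapezoidal AUC and
group-peak maxima of temporal endpoints; ANOVA on log summaries with Tukey
studentized-range adjustment; beta regression (logit link, 10⁻⁵
pseudocount for zero ratios) for compositions; sqrt-/log-transformed
linear models for spatial metrics; pairwise-complete Pearson correlation
matrices.

**Synthetic data** (`vaximg.synth`). Bilateral-limb multi-echo phantoms
with a unilateral high-T2 lesion, PET phantoms with known dose fractions
and forward decay, lymph-node cell tables with follicular spatial
structure and bimodal marker intensities, and peaked temporal endpoint
curves with multiplicative noise — each returning a ground-truth record.

## Worked example

Run the full synthetic demo (simulation → MRI → PET → IMC → spatial →
statistics) from the command line:

```
vaximg run --seed 3 --out demo/
```

Selected output (the full results land in `demo/results.json`, with a
`manifest.json` recording every seed and parameter):

```json
"mri": {
  "enhancement_volume_mm3": 959.8,
  "true_lesion_volume_mm3": 912.0,
  "lesion_mean_t2_ms": 80.07,
  "node_volume_mm3": 33.65
},
"pet": {
  "idg_integral_pct": 7.2,
  "enhancement_volume_mm3": 266.2,
  "total_uptake_pid_mm3_per_g": 2000.0
},
"imc": {"phenotype_accuracy": 0.9993, "fdc_ratio_estimated": 0.0294},
"spatial": {
  "fdc_follicular_b_proximity_mean": 9.48,
  "fdc_follicular_b_nn_distance_um": 3.97
},
"stats": {"auc_fold_change_sam_vs_as01": 3.54, "log_auc_tukey_p": 5.1e-06}
```

Reading the numbers: the thresholded MRI enhancement volume (959.8 mm³)
recovers the simulated 912 mm³ edema lesion within ~5%, and the fitted
lesion T2 (80.07 ms) matches the simulated 80 ms. The PET %ID/g image
integrates to exactly the simulated in-phantom dose fraction (7.2 %ID),
and total uptake is mean %ID/g × enhancement volume. The single-cell
pipeline recovers 99.9% of true phenotypes; each follicular dendritic cell
has on average 9.5 follicular B cells within 15 µm, with a median
nearest-neighbour distance of 4.0 µm. The simulated high-amplitude
platform shows a 3.5-fold AUC increase over the comparator
(Tukey-adjusted p ≈ 5×10⁻⁶) with its group peak at 48 h.

Each stage is also exposed as its own subcommand (`vaximg simulate`,
`vaximg mri fit-t2`, `vaximg pet quantify`, `vaximg radiomics extract`,
`vaximg imc gate|cluster|phenotype|ratios`, `vaximg spatial proximity|nn`,
`vaximg stats auc|max|anova|betareg|lm|correlate`) operating on NIfTI
volumes and CSV tables.

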