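# Methods

This note documents the models implemented in `vaximg`, the defaults and
the reasoning behind choices the underlying measurement conventions leave
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## MR relaxometry

Each voxel of a multi-slice multi-echo acquisition is modelled as a
mono-exponential decay S(TE) = M0·exp(−TE/T2). The default echo grid is
8 echoes at TE = 7…56 ms (7 ms spacing), matching a typical preclinical
MSME protocol at high field; muscle background T2 defaults to 30 ms and
edema-like lesions to 80 ms.

Two fitting routes are provided:

- `log_linear` (default): unweighted ordinary least squares of ln S on TE,
  closed-form and vectorised. Unweighted OLS is used because the vendor
  software whose maps this reproduces does not document its weighting;
  the two routes agree to <0.5% on noiseless data, which the tests check.
- `nonlinear`: per-voxel Levenberg–Marquardt refinement on the exponential
  itself, initialised from the log-linear solution.

A voxel is fitted only when every echo is strictly positive and at or
above `min_signal`; non-positive signals are *excluded*, not clipped,
because clipping biases the log fit. Non-decaying voxels (slope ≥ 0, e.g.
constant signal) get a NaN T2 flag — the relaxation is unidentifiable —
while M0 is still reported from the intercept. A volume with no fittable
voxel raises an explicit error.

Under magnitude-MR noise the log-linear estimator is slightly biased; at
a noise SD of 1% of M0 the median T2 bias across T2 = 20–80 ms stays
below 2% (measured by the acceptance script).

## Enhancement volumetry

The threshold is mean + k·SD (default k = 2) of the voxel intensities in a
contralateral control region; SD is the population SD (ddof = 0) — the
convention is not dictated by the measurement and is fixed here for
reproducibility. Voxels *strictly* above the threshold count ("exceeding"
is read as strict; ties are excluded). Volume = voxel count × voxel
volume, reported in mm³. The same rule serves PET, with the baseline
mean/SD supplied by the caller from the baseline-timepoint scan.

With a Gaussian background, any k = 2 threshold passes ≈2.3% of
background voxels, so volumetry over a search region much larger than the
lesion inflates volume regardless of contrast. The search region is
therefore an anatomically tight muscle-bed ROI around the injection site
(in the demo pipeline, a sphere of 1.4× the lesion radius clipped to the
limb) — the programmatic counterpart of the manually drawn muscle ROI,
which likewise excludes fat, bone and fascial planes via user-supplied
masks rather than automated segmentation.

## PET quantification

Measured activity concentration (dose units per mL) is decay-corrected to
injection time by 2^(Δt/T½); the ¹⁸F half-life is fixed at 109.77 min.
%ID/g = 100 × concentration / net injected dose, with soft-tissue density
taken as 1 g/mL so per-mL equals per-g; residual syringe dose is the
caller's subtraction. Total uptake (glycolytic burden) is the plain
product mean %ID/g × enhancement volume — the product form as defined,
which equals the voxel-wise sum only for a uniform mask (a property the
tests state explicitly). Decay correction and %ID/g conversion are both
scalar multiplications and commute; the whole-phantom integral of
%ID/g × voxel volume must return 100 × the in-phantom dose fraction,
which the acceptance script verifies to ≪0.1%.

## Radiomics features

Only three descriptors are implemented — first-order energy, first-order
IQR and GLDM Dependence Non-Uniformity — the features that proved
informative for immune-response correlation in this pipeline; the broader
feature catalogue is out of scope. Conventions (IBSI-consistent):

- discretisation: fixed bin count (default 32) of equal width over the
  in-ROI min–max range, making DNU invariant to affine intensity
  rescaling (property-tested);
- dependence: for each ROI voxel, the number of 26-connected neighbours
  inside the ROI whose gray level differs by ≤ α (default 0); neighbours
  outside the ROI are ignored, not counted as non-dependent;
- DNU = Σ_d (Σ_g P(g,d))² / N; a single-voxel ROI gives exactly 1;
- percentiles use linear interpolation between order statistics, so the
  IQR oracle is unambiguous (values 1…100 → 49.5).

All three agree exactly with naive-loop implementations on random ROIs of
up to 10³ voxels (acceptance check). Correlation-threshold selection
drops constant features with a logged note rather than reporting r = 0.

## IMC single-cell pipeline

The pipeline consumes a per-cell table (CSV schema: `cell_id, sample_id,
roi_id, x_um, y_um, area_um2, <channel>…`) — segmentation upstream of the
table is out of scope.

1. **z-normalisation** per channel with population SD. Default scope is
   per sample; the normalisation population is genuinely ambiguous in
   practice (per ROI / per section / per study), so pooled scope is a
   flag. Zero-variance channels are an error naming the channel.
2. **Gating**: a two-component univariate Gaussian mixture per channel
   (EM, 5 restarts, seeded). The higher-mean component is "positive"; a
   cell is positive when its posterior for that component exceeds 0.5 —
   the Bayes rule for the fitted mixture, preferred over a hard cut at
   the component intersection. Component separation below 0.1 pooled SD
   flags the channel as degenerate.
3. **Clustering**: K-means (k-means++ init, 10 restarts, seeded) on the
   z-scored channels. Default k = 15: comfortably above the nine defined
   phenotypes so that mixed clusters can split, while keeping clusters
   populated. k is configurable and results should be checked for
   stability around it.
4. **Phenotype assignment** is rule-based and deterministic — the manual
   "inspect and name the cluster" step made reproducible. A channel is
   cluster-positive when >50% of member cells are gated positive; rules
   (e.g. follicular dendritic cell = CD21+CD20−) are evaluated in an
   explicit priority order, most specific first, so a follicular B cell
   (CD20+Bcl6+) is not swallowed by the generic B-cell rule (CD20+).
   Ambiguity at equal explicit priority is an error, never silently
   resolved. Unmatched clusters are "unassigned".
5. **Ratios**: per-sample phenotype counts over all ROIs of the sample,
   divided by total cells, unassigned included, summing to 1.

## Spatial metrics

Distances are 2-D centroid-to-centroid in µm on the per-sample mosaic
(sections are 2-D; a membrane-to-membrane convention would need the
segmentation masks the table does not carry). Proximity counts B cells
within 15 µm of each A cell, boundary *inclusive* ("15 or less"); the
nearest-neighbour metric is the median over A cells of the distance to
the closest B (self-pairs excluded when A = B). Cells from different ROIs
of a sample interact through global mosaic coordinates; cross-sample
distances are never computed. Edge effects at section borders are not
corrected. An absent phenotype yields a flagged undefined result, never a
silent 0. The KD-tree implementation is checked against an O(n²)
brute-force oracle for exact equality.

## Temporal statistics

- **AUC**: trapezoidal, over observed timepoints as-is — no baseline
  subtraction and no extrapolation. This is recorded prominently because
  fold-change ratios of AUCs depend on the rule; with a zero baseline the
  two conventions coincide. Missing timepoints are dropped and flagged;
  nothing is imputed.
- **Group maximum**: the peak timepoint is the argmax of the group-mean
  curve; all subjects of the group are read at that shared timepoint, so
  groups are compared at their average-curve peaks. Ties resolve to the
  earliest timepoint and are logged.
- **ANOVA / Tukey**: linear model on log summaries with treatment (and
  optionally cohort and interaction); every pairwise treatment contrast
  gets studentized-range (Tukey) adjusted p-values and simultaneous CIs,
  even though typically only prespecified contrasts are interpreted.
  Marginal means average over cohort levels with equal weight.
- **Beta regression**: logit-linked mean with a single common precision
  φ, fitted by maximum likelihood (statsmodels `BetaModel`); Wald
  pairwise comparisons, unadjusted (prespecified). Ratios of exactly 0
  enter as the 10⁻⁵ pseudocount; ratios of exactly 1 are shrunk to
  1 − 10⁻⁵ symmetrically, a choice this package fixes since only the zero
  rule is conventionally stated.
- **Transformed linear models**: OLS on √(proximity) or log(NN distance)
  with a treatment effect, unadjusted pairwise t-tests.
- **Pearson matrices** are pairwise-complete; constant columns or pairs
  with <3 complete observations give NaN, flagged rather than 0.

## Synthetic-data generator

The generator provides the study conditions for every test:

- **MR phantom**: two parallel limb cylinders (air outside), a spherical
  lesion only in the right limb, optional lymph-node sphere. Cylinders
  and spheres are used deliberately: their volumes are analytic, so
  volumetry oracles are closed-form. Noise is additive Gaussian by
  default — the downstream estimators assume no particular noise model,
  and Gaussian keeps the noiseless signal exactly within the fitted model
  class — with Rician magnitude noise available as an option.
- **PET phantom**: a single static frame (one uptake image per session;
  no time-activity curves), with dose fractions (default 2% lesion, 0.2%
  node, 5% diffuse background) spread uniformly over their regions and
  forward-decayed by 2^(−Δt/T½), so the correction step can be verified
  exactly. Fractions summing above 1 are rejected.
- **Cell tables**: default 10,000 cells over a 1×1 mm field with 5
  follicles. Each cell has exactly one true phenotype drawn from a
  B-cell-dominated composition (25% B, 15% follicular B, 15% helper T,
  12% CD8 T, 10% APC, 8% phagocyte, 4% Treg, 4% Tfh, 3% FDC, 4%
  markerless); marker channels are bimodal Gaussian (negative 1.0 ± 0.3,
  positive 8.0 ± 1.2 a.u.), i.e. well-separated as after good staining.
  FDCs sit at follicle centres, follicular B and Tfh cells disperse
  around them (40 µm SD), other types are uniform.
- **Endpoint series**: group-mean curves are log-normal-shaped pulses
  (zero at baseline), defaults mimicking a platform comparison — a
  high-amplitude late-peaking group (peak 48 h) vs. a lower-amplitude
  24 h-peaking group, with low-amplitude carrier controls treated simply
  as small pulses. Per-subject noise is multiplicative mean-one lognormal
  (default CV 0.2), n = 4 per treated group.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: anatomy and partial-volume
effects, scanner artifacts and k-space physics, Rician bias at low SNR
(unless enabled), PET reconstruction/attenuation effects, spillover
between IMC channels, segmentation errors, cell-density gradients beyond
follicles, and biological correlation between channels within a cell
beyond the phenotype rules.

All generators are bit-reproducible under a fixed seed, and with all
noise parameters at 0 the downstream estimators are exact to floating
point — both properties are under test.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit seed; the demo pipeline derives
per-stage seeds from the single config seed and records them in a
manifest with all parameters and library versions. Rerunning the same
config reproduces every numeric output bit-identically.

The acceptance script uses problem sizes chosen to make each check
statistically meaningful while keeping a full run in the order of tens of
seconds: 4,096 voxels per relaxometry condition, ~10⁵-voxel phantoms for
volumetry and conservation, 100 random instances of up to 2,000 cells for
the spatial oracles, 10,000 cells for phenotyping recovery, 500 null and
200 alternative simulations for the ANOVA calibration, and n = 30/group
for beta-regression recovery.

## Known limitations

- Mono-exponential T2 only: no multi-compartment relaxation, B1 or
  stimulated-echo correction, and no registration between timepoints.
- PET: no reconstruction, attenuation/scatter handling, SUV
  normalisation or kinetic modelling; unit consistency between dose and
  volume is the caller's responsibility.
- The rule-based phenotype assignment is only as good as the gating;
  channels with weak separation are flagged but still gated.
- Spatial metrics ignore section-border edge effects, which bias
  proximity counts downward near borders for sparse types.
- The beta regression uses a common precision; composition-dependent
  dispersion is not modelled.
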