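# Methods

`petradiomics` implements a clinico-radiomic modelling pipeline for
predicting pathologic complete response (γpCR, Mandard tumor-regression
grade 1 vs. 2–5) to neoadjuvant chemoradiotherapy in esophageal cancer from
pre-treatment ¹⁸F-FDG PET: radiomic feature extraction from an SUV volume
and tumor mask, correlation-based feature reduction, logistic model building
with HER2/CD44 biomarker augmentation, and bootstrap internal validation.
Because no per-patient data are public, the pipeline is exercised end-to-end
on synthetic inputs whose marginals match the published cohort, plus the
published contingency tables, which are bundled as exact count fixtures.

## Radiomic features

The extractor emits exactly 101 features in seven families: 19
morphological, 2 local-intensity, 18 intensity-statistical, 25 gray-level
co-occurrence (GLCM), 16 run-length (GLRLM), 16 size-zone (GLSZM) and 5
neighbourhood gray-tone difference (NGTDM) features. The family membership
follows the canonical IBSI-style lists trimmed to these counts; beyond the
named conventional metrics (volume, TLG, SUVmax, SUVpeak, SUVmean) and the
named model candidates (Moran's I, Geary's C, GLCM inverse variance, second
measure of information correlation, NGTDM coarseness, elongation, long-run
low gray-level emphasis), the exact membership is this implementation's
documented choice, not an externally fixed fact.

Key conventions, all configurable through `ExtractionConfig`:

* **Discretization** — fixed-bin-size with w = 0.5 SUV by default (a common
  choice for FDG PET), `level = floor((SUV − min)/w) + 1`; fixed-bin-number
  (equal-width bins over the in-mask range) is available and makes the
  discrete texture families exactly invariant to intensity shifts.
* **Texture aggregation** — GLCM and GLRLM are computed over the 13 unique
  3D directions at distance 1; per-direction feature values are averaged
  (merged-matrix variant by option). GLSZM zones and NGTDM neighbourhoods
  use 26-connectivity. This makes all direction-aggregated texture features
  exactly invariant under axis-aligned 90° rotations of an
  isotropic-spacing volume (a tested property).
* **Spatial autocorrelation** — Moran's I and Geary's C over in-mask voxel
  intensities with inverse-Euclidean-distance weights in mm. The double sum
  is O(N²) and computed exactly for ROIs up to 20 000 voxels; larger ROIs
  are reduced by a deterministic intensity-stratified subsample (flagged in
  the feature metadata). For any two-voxel ROI with distinct values the
  statistics are algebraically forced to I = −1, C = 1, which the suite
  asserts for arbitrary values.
* **SUVpeak** — the maximum over in-mask centres of the mean SUV in a 1 cm³
  sphere (radius 6.204 mm) of in-grid voxel centres; the second
  local-intensity feature is the sphere-mean at the hottest voxel (the
  larger sphere-mean on ties). Near the grid boundary the truncated sphere
  averages fewer voxels, so the global peak can exceed the hottest-voxel
  peak; both are reported.
* **Morphology** — mesh volume and surface area from marching cubes at
  level 0.5 on the binary mask; principal-axis lengths, elongation
  √(λ₂/λ₁) and flatness √(λ₃/λ₁) from the eigenvalues of the voxel-centre
  covariance; TLG = SUVmean × voxel volume. The faceted mesh of a binary
  mask slightly overestimates a smooth surface's area, so a digitized
  sphere's sphericity plateaus near 0.92 rather than reaching 1 — a known
  property of mesh-on-binary pipelines, not an error.
* **Undefined values** — features whose defining sum is empty (GLCM
  correlation of a constant region, mesh metrics of a single voxel, the
  NGTDM coarseness 1/ε cap with ε = 1e-12) are reported as NaN with a
  reason flag, never silently zeroed, so downstream screening can exclude
  them explicitly. Where a formula forces a value (inverse variance with a
  single gray level = 0), the forced value is reported.

Every texture and autocorrelation feature is verified against an
independent naive-enumeration implementation on 200 random grids up to
5×5×5 at tolerance 1e-8.

## Feature reduction

Features are clustered by average-linkage agglomerative clustering on the
distance d = 1 − |ρ|, ρ the Spearman rank correlation between feature
columns. The absolute value makes redundancy sign-agnostic (the signed
variant is an option). Clusters are subtrees lying entirely below a cut at
0.6 × the maximum linkage height — standard dendrogram-cut semantics for a
"below 60% of the maximum linkage" rule. From each cluster the feature with
the lowest univariable likelihood-ratio p against the outcome is kept
(1 df χ², intercept-only null; ties broken by feature name for
reproducibility), and representatives with p ≥ 0.2 are dropped. Patients
are clustered with the same machinery on the per-feature Z-scored,
transposed table.

## Models

Twelve logistic models: M1 = histology + clinical T-stage (dichotomized
adenocarcinoma/squamous and T1-2/T3-4a); M2 = the L1-selected radiomic
features; M3 = M1 ∪ M2; M4–M6 add HER2, M7–M9 add CD44, M10–M12 add both.
Marker models use complete cases for the markers involved (mirroring the
two patients with indeterminate HER2 in the published cohort). The L1
penalty is used only for selection — the penalty weight is tuned by
5-fold outcome-stratified cross-validated binomial deviance on a log-spaced
grid (minimum-deviance rule; a 1-SE rule is an option) — and the final
models are ordinary maximum-likelihood logistic fits, so AIC = 2k − 2LL is
on the usual scale. Quasi-complete separation is detected by coefficient
divergence and flagged rather than silently accepted; no penalized fallback
is applied by default. An empty L1 selection is legal and flagged; the
pipeline then falls back to the best-p representative so that M2 exists.

## Internal validation

Per model the report carries Nagelkerke R² (Cox–Snell rescaled by its
maximum), Brier score, Mann-Whitney AUC with ties counted ½, discrimination
slope (mean predicted risk in events minus non-events), calibration
intercept (calibration-in-the-large: intercept refitted with the slope
fixed at 1 via an offset logistic model) and calibration slope (from
y ~ a + b·logit(p̂)). Optimism correction is Harrell's bootstrap: each
resample — stratified on the outcome to reduce one-class resamples —
refits the model per the refit policy (default: refit the coefficients of
the fixed covariate set; a full-pipeline policy that re-runs selection
inside the resample is supported via a callable), is scored on itself and
on the original sample, and corrected = apparent − mean(boot-apparent −
boot-test). Failed refits are dropped and counted; more than 20% failures
is a hard error. Two numerical guards keep the calibration measures sane:
recalibration coefficients from a separated fit (non-finite or beyond ±50
on the logit scale) are treated as undefined, and optimism is averaged per
measure over the resamples where that measure is defined, with excluded
counts surfaced in the report flags. The production default is B = 20 000
repetitions; tests
and the demo analysis use B between 300 and 2 000, at which doubling B
moves corrected AUC by well under 0.005.

**Known limitation.** The regular optimism bootstrap evaluates boot models
on the original sample, which overlaps each resample by ~63%. Under extreme
overfitting (many noise predictors, small n) the estimated optimism
therefore falls short of the true optimism and corrected discrimination
retains a residual upward bias: in a pure-noise design with 10 predictors
and n = 60, corrected AUC typically lands between 0.45 and 0.61 instead of
exactly 0.5, and unusually overfit draws can remain near 0.7. This is a
property of the estimator, shared by any faithful implementation, and is
why external validation is still required of any model the pipeline
produces.

## Biomarkers

HER2 immunohistochemistry is dichotomized by the guideline rule (0 →
negative, 3+ → positive, 1+/2+ resolved by FISH, missing without FISH).
CD44, cytosolic HIF1α and PTCH1 arrive as already-dichotomized 15-point
immuno-reactivity scores (the cut-point is a config field, consumed as
given); nuclear HIF1α and SHH are present/absent. Diagnostic metrics carry
exact Clopper–Pearson intervals. Fisher's exact test uses the two-sided
point-probability convention (all tables at fixed margins whose probability
is ≤ the observed one, with a 1e-7 relative tolerance guard), verified
against full hypergeometric enumeration. Under this convention the bundled
CD44 × T-stage table {(1,15),(5,22)} gives p ≈ 0.386; a published rounding
of 0.35 for these counts is not reproducible under the standard convention
and the discrepancy is recorded here rather than resolved.
Cluster-covariate association uses Pearson χ², switching to an exact
alternative (Fisher for 2×2, seeded permutation otherwise) when more than
20% of expected cells are below 5.

## Synthetic data

The generators define the study conditions rather than emulate real
anatomy:

* **Phantoms** — a constant-SUV ellipsoid (base 6 SUV, radii 18/14/12 mm on
  a 48³ grid at 2 mm isotropic spacing) plus a smoothed Gaussian random
  field (correlation length 6 mm, amplitude 1.5 SUV) and white noise
  (0.2 SUV), clipped at 0 since SUV is nonnegative. A GRF gives
  controllable spatial autocorrelation — exactly the structure Moran's I /
  Geary's C and the texture families measure — with no attempt at scanner
  PSF, reconstruction or anatomy.
* **Cohorts** — 96 patients by default; response prevalence 0.22, HER2+
  0.19, CD44+ 0.63 and clinical-indicator frequencies matching the
  published marginals; 101 radiomic features in 7 equicorrelated blocks
  (within-block Spearman ρ = 0.8 by default, converted to the Gaussian
  Pearson scale via ρ_P = 2·sin(πρ_S/6)); outcomes Bernoulli(expit(Xβ))
  with the generating β stored, and the intercept tuned by root-finding to
  the target prevalence unless given explicitly. Markers and features are
  generated independently by default, mirroring the observed independence
  of imaging phenotype clusters and marker status; dependence is opt-in
  through β. Because no per-patient feature values were ever published,
  the synthetic effect sizes are free parameters chosen for testability —
  passing tests demonstrate correctness of the machinery under known truth,
  not fidelity to any real cohort.
* **Count fixtures** — the published 2×2 tables (HER2/CD44 × response and
  × T-stage) bit-exactly, and deterministic 96- and 43-patient clinical
  tables that reproduce every published pairwise margin; joint cells that
  were never published are filled by a fixed feasible assignment and the
  tables are labelled synthetic.

Every stochastic operation is a pure function of its spec including the
seed; the pipeline fans a master seed out to per-stage seeds by fixed
offsets so stages can be re-run in isolation.

## Problem sizes in the bundled runs

The demo analysis and the test suite run at desk scale by choice: phantoms
of ~1 600 in-mask voxels, cohorts of 96–2 000 patients, bootstrap depths of
300–2 000, 200 oracle grids, and 200 replicates for parameter recovery.
The published-count worked examples (diagnostics, Fisher tests, LRT
p-values) are exact and independent of scale.
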