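# Methods

`srtrad` implements an MR-radiomics framework for early prediction of local
failure (LF) of brain metastases treated with hypo-fractionated stereotactic
radiotherapy (SRT), exercised end-to-end on a synthetic imaging cohort. This
note records the model, its assumptions, the tunable parameters, and the
design decisions taken where the procedure admitted more than one reading.

## The prediction problem

Each lesion is observed on two co-registered MR sequences (T1w with
gadolinium contrast, T2-FLAIR) at two timepoints: baseline (before SRT) and
first follow-up (within ~3 months). The outcome is the lesion's local
status — local control (LC) or local failure (LF) — at three horizons
(overall, 6-month, 12-month). The hypothesis embodied by the framework is
that early post-treatment *changes in texture*, particularly in the regions
surrounding the tumour, anticipate eventual failure long before a change in
size is measurable.

## Sub-lesion regions

Four disjoint analysis regions per lesion (`srtrad.masks`):

* tumour — contrast-enhancing disease on T1w;
* edema — peritumoural T2-FLAIR hyperintensity;
* tumour-margin — a 3 mm Euclidean ring around the tumour, excluding
  tumour and edema;
* lesion-margin — a 3 mm ring around tumour ∪ edema.

Margins are built by thresholding the Euclidean distance transform in
physical units, which is exactly ball dilation and independent of grid
anisotropy. The margin width is configurable (1/3/5/10 mm are the sweep
values of interest; 3 mm is the default). Whether the tumour-margin should
exclude edema is genuinely ambiguous; we exclude it (config switch
`margin_excludes_edema`, default true) so the four regions are disjoint
analysis units. A tumour-margin fully swallowed by thick edema is retained
empty and flagged; its features propagate as missing values, never as
silent zeros.

Anisotropic acquisitions (e.g. 0.5 mm in-plane, 1.5/5 mm slices) are
brought to 0.5 mm isotropic grids by linear interpolation along the slice
axis (nearest-neighbour for masks) before 3D feature extraction.

## The 3072-feature catalog

Features are computed per (region × sequence) block — 4 × 2 = 8 blocks of
384 features:

| family | count | notes |
|---|---|---|
| geometric | 8 | volume, surface area, max 3D diameter, sphericity, compactness, convexity, elongation, flatness — from the binary mask |
| first-order histogram | 16 | mean…IQR on original-image intensities |
| LBP histogram | 16 | the same 16 statistics over 2D LBP codes (P=8, R=1, axial slices) |
| GLCM | 24 | Haralick-style catalog; 32 grey levels, distance 1, 13 pooled 3D directions, symmetric, normalized |
| wavelet | 8 × (16 + 24) | first-order + GLCM on each of the 8 single-level 3D sub-band images (Haar by default) |

8 + 16 + 16 + 24 + 320 = 384 per block; 3072 in total. The per-family
decomposition is this package's reconstruction of a catalog whose printed
description gives the total and example statistic names; the catalog here
is the binding definition for this artifact, contains every named
statistic, and reproduces the printed total exactly.

Every feature is reported as relative change from baseline,
Δf = (f_FU − f_BL) / (|f_BL| + ε), with ε = 1e-9 × the mean absolute
in-mask baseline intensity, winsorized at ±10 so near-zero baselines
cannot dominate rank statistics.

Numerical conventions worth knowing:

* GLCM quantization is equal-width over the in-mask range, so GLCM features
  are invariant to affine intensity maps; fewer than two occupied levels is
  degenerate → missing.
* LBP neighbours are ordered clockwise from east with a ≥-centre
  comparison (bit i = 2^i), computed per axial slice with edge replication
  at borders; codes are raw 8-bit values, invariant to strictly increasing
  intensity transforms.
* Wavelet sub-bands are reconstructed back to the original grid (inverse
  transform with the other seven bands zeroed) so the sub-lesion masks
  apply unchanged; the eight band images sum to the original image.
* First-order entropy uses 32 equal-width bins over the in-mask range
  (scale-invariant); a constant region has entropy 0.
* Convexity is the voxel-count ratio of the mask to its rasterized convex
  hull, matching a brute-force hull oracle exactly; coplanar masks have no
  3D hull and yield a flagged missing value.
* Extraction operates on an even-aligned bounding box of the lesion so the
  wavelet phase does not depend on where the lesion sits in the volume;
  the vectorized per-filter path computes in float32 (the scalar reference
  path, against which it is tested, is float64).

## Feature reduction and selection

1. **Correlation reduction** — Pearson R² for every feature pair
   (pairwise-complete when values are missing); clusters = connected
   components of the R² > 0.8 graph; representative = largest dynamic range
   (max − min over lesions). Connected components are used because they are
   deterministic and order-independent; constant features form singletons
   and can never shadow a varying clustermate. On 100-patient synthetic
   cohorts this step reduces 3072 to roughly 900 features.
2. **Ranking** — for each of 50 leave-one-fold-out subsets of an
   outcome-stratified 50-way patient partition, the two-sided Mann-Whitney
   U p-value per feature; features ranked by frequency in the per-subset
   top-15, ties by median p, then name. Note the 50 subsets share ~96% of
   patients, so the per-subset lists are strongly dependent: frequency
   measures stability of the ranking, not independent evidence.
3. **Forward selection** — greedy growth over the top-15 pool scored by the
   bootstrap .632+ AUC of an SVM (250 bootstraps by default). Each
   bootstrap draws *patients* with replacement after patient-level random
   under-sampling of the majority class; out-of-bag patients form the test
   set; the out-of-bag AUC is floored at 0.5 (the no-information rate for
   AUC), the overfitting ratio R = (AUC_resub − AUC_test)/(AUC_resub − 0.5)
   is clipped to [0,1], w = 0.632/(1 − 0.368 R), and the blend is
   (1−w)·AUC_resub + w·AUC_test, averaged over bootstraps. AUC ties during
   greedy growth resolve in favour of the better-ranked feature.
4. **ANOVA minimal set** — one-way ANOVA across the per-size bootstrap AUC
   samples of the greedy prefixes (sizes 1..argmax); if significant at
   α = 0.05, each smaller size is compared with the best by Tukey's HSD and
   the smallest size not significantly worse is the optimal biomarker. A
   non-significant ANOVA means the sizes are indistinguishable and the
   single best-ranked feature suffices.

All resampling respects patient boundaries: the lesions of one patient are
never split across a train/test divide, and standardization / median
imputation statistics come from training rows only (asserted by tests).

## Outcome prediction and risk assessment

Leave-one-patient-out (LOPO): each held-out patient's lesions are labelled
by the majority vote of 250 SVMs, each trained on a balanced patient
bootstrap of the remaining patients. A Gaussian kernel is used for the
overall and 12-month outcomes and a linear kernel for the 6-month outcome;
C = 1 and the kernel width 1/(p·Var) are the package defaults since the
procedure leaves them open. An exact 50/50 vote is called LF, favouring
sensitivity for the clinically actionable event; LF is the positive class
throughout. Metrics (accuracy, sensitivity, specificity) pool lesions.

Risk assessment splits lesions (clinical local control) or patients
(overall survival; a patient is in the LF cohort as soon as one lesion is
predicted LF) by their cross-validated predicted outcome and compares
Kaplan-Meier curves with the log-rank test, with administrative censoring
at five years. KM/log-rank are computed by lifelines behind this surface;
the tests verify them against hand-computed product-limit and O−E tables.
Tied event/censor times follow the standard convention (censoring after
events).

## The synthetic cohort

No clinical images are distributed, so `srtrad.cohort` generates the study
conditions: 100 patients with 1–3 lesions (probabilities 0.73/0.20/0.07,
≈134 lesions expected), ≈40% overall LF, survival times exponential with
hazard 0.045/month (LC patients) vs 0.135/month (patients with ≥1 LF
lesion; hazard ratio 3), independent exponential censoring (0.02/month)
and administrative censoring at 60 months. LF lesions carry a
time-to-failure drawn from a truncated exponential (0.15/month) within the
follow-up window; 6-/12-month labels derive from it, and LC lesions whose
patient died before the horizon are flagged `excluded` rather than
silently dropped.

Each lesion is a spherical tumour core (radius 2–3 mm) with an edema shell
(1–2.5 mm) on a 36³ grid of 0.5 mm voxels — deliberately scaled-down
phantoms (clinical lesions average ~2.1 cm) chosen so that a 3 mm margin
ring fits the volume and multi-seed studies run at desk scale; the
geometry is identical at both timepoints, so geometric features carry zero
relative change on synthetic data (a real study would recontour at
follow-up — a known limitation of the phantom). Intensities are zone-wise
constant (background/tumour/edema levels per sequence) plus a stationary
Gaussian random field (0.5 mm correlation length), with per-lesion latent
offsets of each zone's mean (s.d. 6 intensity units) and noise amplitude
(s.d. 20%). Zone sample moments are pinned exactly, so the latents are the
sole carriers of mean/amplitude variation.

**Planted effects.** A texture control names a (zone, sequence, mean|sigma)
triple. For LF lesions, at follow-up only, the control's latent is shifted
by d·√2·(latent s.d.) — and the follow-up amplitude is expressed as
baseline × (1 + g) — so the relative change of the control's first-order
feature differs between classes by exactly the standardized effect size d
(default 1.5; verified to be recovered within the ±0.3 contract at
n = 100). The five default controls perturb edema-T2 amplitude,
margin-T2 mean, tumour-T2 mean, edema-T1 mean and margin-T1 amplitude.
Because a latent shift alters *every* intensity-derived feature of the
affected (region, sequence) block — histogram and GLCM on the original and
wavelet-band images, and even LBP through comparisons across zone
boundaries — and forward selection typically prefers a wavelet or GLCM
derivative over the first-order feature the control is named after,
planted-effect recovery is attributed at block level
(`cohort.attributable_features`, `cohort.recovered_controls`); geometric
features (time-invariant masks) are never attributed.

What the phantom does **not** emulate: MR physics (bias fields, motion,
partial volume), registration error, segmentation variability, lesion
growth/shrinkage, and any realistic relationship between texture and
biology. Passing tests therefore demonstrate that the *pipeline* recovers
controlled signal and stays calibrated under the null — not that the
clinical effect sizes are reproducible.

## Calibration, bias, and what the null tests mean

Feature selection runs on the full sample, exactly as in the emulated
procedure (selection before cross-validation). Under the null this is
optimistically biased *by construction*: the forward search maximizes the
.632+ AUC over hundreds of candidate features, so the selected set's AUC —
and the LOPO accuracy of a biomarker selected on the same lesions — sits
above 0.5 even for pure noise. The null-calibration tests therefore fix a
pre-specified feature set and verify that the .632+ estimator and LOPO
accuracy are at chance (0.5 ± 0.1) and that the marginal Mann-Whitney
false-positive rate is ~5%. Two small-sample artifacts are worth knowing:
flooring the out-of-bag AUC at 0.5 inflates the null mean when out-of-bag
sets are tiny (we calibrate at 60 patients where the artifact is
negligible), and MWU p-values are discrete for very small class counts,
deflating the false-positive rate.

## Problem sizes and defaults

| parameter | default | where |
|---|---|---|
| margin width | 3 mm (1/3/5/10 supported) | `make_margin_masks` |
| R² threshold | 0.8 | `correlation_reduce` |
| ranking folds / top-k | 50 / 15 | `rank_features_mwu` |
| forward-selection pool | 15 | `forward_select` |
| bootstraps | 250 (study); 50 in the desk-scale studies | `fit(n_bootstrap=…)` |
| GLCM levels / distance / directions | 32 / 1 / 13 pooled | `GLCMSpec` |
| wavelet | Haar (configurable) | `band_images` |
| SVM | C=1, γ=1/(p·Var); RBF (overall, 12-mo), linear (6-mo) | `ClassifierSpec` |
| cohort | 100 patients, 36³ @ 0.5 mm, d=1.5, LF≈40% | `CohortConfig` |

The multi-seed studies (parameter recovery over 10 seeds at 100 patients,
null calibration over 10 seeds at 60 patients, stratification power over
20 seeds at 100 patients) use 50/20 bootstraps; these sizes are the
package's choice of a desk-scale experiment and are stated alongside each
result. In the stratification study the clinical local-control comparison
(lesion level) separates essentially always, while the overall-survival
comparison (patient level, OR-rule) has ~75% power: predicted cohorts mix
~20% of each true class, the resulting hazard mixture is
non-proportional, and a third of control patients are censored — the
survival signal is intrinsically the weaker of the two analyses.
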