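# Methods

## Problem and scope

The package implements a CT-based prediction pipeline for binary PD-L1
expression in non-small cell lung cancer. PD-L1 status is the tumor
proportion score dichotomized at 1% (`label = (TPS ≥ 1)`, boundary
inclusive). Three models are built and compared on a chronological 7:3
train/validation split: a clinical logistic model, a radiomics signature
(Rad-score) and a deep-learning-radiomics signature (DLR-score). Because
no patient-level hospital data is distributable, the pipeline is
validated on synthetic phantom cohorts with known generating truth; the
published signature coefficient sets (in `radsig.reference`) serve as
fixed worked examples for the scoring path.

## Phantom generator (`syndata`)

Each patient is a small CT-like volume (default 32×48×48 voxels at
1.5×0.7×0.7 mm — thin-slice, anisotropic) containing one ellipsoidal
nodule with a radius drawn from 5–12 mm. Background is a smooth
low-intensity field near −880 HU; nodule interiors sit in the
soft-tissue range (+20 HU) with a correlated Gaussian texture produced by
smoothing white noise with a Gaussian kernel and rescaling the variance.
The positive class has a shorter correlation length (2.0 → 2.0/(1+c)
voxels) and a larger standard deviation (60 → 60·(1+c/2) HU), with
contrast `c = 1.5` by default — strong enough that co-occurrence and
size-zone statistics separate the classes, which is the property the
downstream stack is tested against. Intensities are clipped to
[−1000, 400] HU so min-max normalization is exercised realistically.

Labels are drawn from a logistic model on the clinical covariates
(`clinical_effects` are log-odds per raw covariate unit, covariates
centered; intercept calibrated to the target prevalence). The default
prevalence is 61/259 ≈ 0.235, matching the cohort composition the
pipeline emulates. TPS is a logistic-normal percentage drawn *truncated
to the label's side of the 1% threshold*, so dichotomization reproduces
the generating labels exactly while both classes keep distributional
mass. The second observer's mask is the first mask dilated or eroded
(seeded coin flip) by `observer_perturbation` voxels. Study dates
increase with patient index, making the chronological split reproducible.

The pure feature-table generator draws standard-normal features in
correlated blocks (pairwise ρ within a block) and labels with logit
`effect × Σ(informative features)` — `effect` is the per-feature
log-odds, so with the default recovery setting (n=500, 5 informative of
50, effect 1.5) a strong but imperfect signal results (held-out AUC
≈ 0.93 for the fitted signature).

What the phantoms do *not* emulate: anatomy, scanner physics, partial
volume and reconstruction kernels, segmentation ambiguity beyond
morphological perturbation, or realistic feature covariance. Passing
tests therefore demonstrate correctness and statistical behaviour of the
pipeline, not clinical performance on real CT.

## Image handling (`imagio`)

Axis convention is `(slice, row, column)`, 0-based, everywhere; spacing
is stored in the same order in mm. DICOM series and NIfTI are read
through SimpleITK. Preprocessing for the deep-feature branch follows the
largest-area rule: pick the axial slice with the most tumor voxels (ties
→ lowest index), min-max normalize the slice to [−1, 1]
(`2(x−min)/(max−min) − 1`; constant slices are an error), crop to the
mask bounding box with an 8-pixel margin (configurable; the tight-vs-
margin choice is not standardized, a small context border is
conventional) and bilinearly resize to 224×224 using the half-pixel-
center convention. No resampling to isotropic voxels is performed by
default (features are extracted from native thin-slice geometry).

## Texture engine (`texture`)

Discretization: fixed bin width 25 HU on HU-scaled images (original,
wavelet, LoG) and fixed bin count 16 after the non-HU filters
(exponential, square-root, LBP-3D); levels are integers from 1, with
`level = floor((x − min_VOI)/width) + 1` in width mode. All matrix
builders see only the mask bounding box, which changes nothing but
speed.

- **GLCM** — co-occurrences at distance 1 along the 13 unique 3D
  directions, symmetrized and pooled into one matrix before normalizing
  (direction pooling makes the features invariant to axis-aligned
  rotations; a custom offset subset can be passed for per-direction
  work). ClusterProminence is Σ(i+j−μx−μy)⁴p(i,j).
- **GLSZM** — zones are 26-connected components of constant gray level
  (scipy.ndimage labelling); small-area emphasis, size-zone
  non-uniformity, small-area-low-gray-level emphasis, zone variance (over
  the zone-size marginal) and zone percentage follow the standard count
  normalizations by the number of zones.
- **NGTDM** — per level, `s_i` accumulates |level − mean of in-VOI
  neighbours| over the 26-neighbourhood (8 in 2D); voxels without in-VOI
  neighbours are excluded, and a stricter full-neighbourhood-only rule is
  available. Busyness/Coarseness/Contrast/Complexity/Strength use the
  classical definitions with sums over occupied levels; degenerate
  denominators (≤1 occupied level) yield 0.
- **First order** — population moments: skewness m₃/m₂^1.5, kurtosis
  m₄/m₂² (non-excess; normal → 3). Zero-variance input gives skewness 0
  and kurtosis NaN with a warning; inside a cohort run a failing feature
  class emits NaN rather than aborting the patient.
- **Filter bank** — one-level stationary Coiflet-1 3D wavelet (8
  sub-bands named H/L per axis in (axis0, axis1, axis2) order; odd axes
  edge-padded then cropped); Laplacian-of-Gaussian at σ = 2 mm converted
  per-axis to voxels, applied to the mean-centered volume so the DC
  response is exactly zero (the truncated discrete kernel otherwise has a
  small nonzero gain); exponential `exp(|x|/max|x|)`; signed square root
  `sign(x)·√|x|`; and LBP-3D.
- **LBP-3D** — this family has no single standard definition. The
  implementation is a deliberately lightweight rotation-invariant
  variant on the radius-1 sphere: `m1` = mean sign occupancy of the 26
  neighbour differences, `m2` = magnitude of the dipole (first-moment)
  vector of the sign pattern, `k` = kurtosis of the neighbour-difference
  distribution. It is feature-flagged and excluded from the brute-force
  oracle suite, which covers the three matrix families.

Every matrix builder is checked against an independent enumeration
oracle (explicit pair loops, flood fill, per-voxel neighbour scans) on
seeded VOIs up to 6³ at 1e-9 tolerance.

## Deep-feature contract (`embed`)

The DLR branch consumes a fixed-length embedding of the 224×224 crop —
2048 values named `DL_1..DL_2048`, the dimensionality of a global-
average-pooled ResNet-50. The shipped embedder is a deterministic stub:
16×16 average pooling, a seeded random linear projection, and tanh. It
preserves coarse texture statistics through the pooling stage (the
phantom classes remain separable end to end) and makes the pipeline
testable without pretrained weights; `register_embedder` is the plug-in
point for a real backbone, which is intentionally not on the tested
path. The crop is single-channel; channel replication is an adapter
concern.

## Selection stack (`select_sig`)

Z-score parameters (mean, n−1 sd) are fitted on training patients only
and applied unchanged to validation; constant features are dropped with
a warning. Inter-observer stability uses ICC(2,1) — two-way random
effects, absolute agreement, single rater,
`(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)` — computed on a
dual-observer subset (default 30 training patients); features with
ICC ≤ 0.75 are dropped. Pearson pruning scans features in descending
|point-biserial correlation with the label| (ties by name) and drops any
feature with |r| > 0.90 against an already-retained one.

The LASSO is an ℓ1-penalized binomial log-likelihood
`(1/n)Σ[log(1+e^η) − yη] + λ‖β‖₁` solved by cyclic coordinate descent
inside an IRLS quadratic approximation (weights clipped below at 1e-5),
intercept unpenalized, convergence at max coefficient change < 1e-7,
hard cap 10⁴ sweeps with a diagnostic error. An active-set strategy
(sweep the active set to convergence, then a vectorized KKT check over
the rest) makes the 2048-feature DLR problem fast while remaining
equivalent to full cyclic descent. A Gaussian variant is kept for the
orthonormal-design soft-threshold closed form. λ is chosen by 5-fold
label-stratified, seeded CV minimizing mean binomial deviance over a
geometric grid from λ_max = max|xᵀ(y−ȳ)|/n down by 10³ (10² when
p ≥ n, following glmnet's convention); the 1-SE rule is available via
config. Top-k retention truncates to the k largest |coefficients|
without refitting (refit available behind a flag), mirroring the
post-hoc rule-of-thumb narrative of the 19 → 15 deep-feature reduction.
The score is `intercept + Σ coef × feature` on the model's normalized
scale; the loader accepts the `Zone%` alias for `ZonePercentage`.

## Clinical model (`clinmodel`)

Univariate screen: continuous variables get a two-sample t-test when
both classes pass Shapiro–Wilk at 0.05, otherwise Mann–Whitney;
categorical variables get Pearson χ² (no continuity correction) unless
an expected cell is below 5, then Fisher's exact (2×2). Variables with
p < 0.05 enter a multivariate logistic regression (Newton/IRLS via
statsmodels) reported with odds ratios and 95% Wald CIs; perfect
separation and collinearity are detected and raised. An empty screen
falls back to an intercept-only model with a warning.

## Evaluation statistics (`evalstats`)

AUC is the Mann–Whitney probability with ties counting one half —
identical to the trapezoidal ROC area — with DeLong variance from
placement values and a 95% normal CI clipped to [0, 1] (clipping is
applied and visible in the stored bounds). The paired DeLong test uses
the placement-value covariance; identical score vectors are a degeneracy
error, while a rank-preserving transform (identical placements, equal
AUCs) returns z = 0, p = 1. Classification uses `score ≥ cutoff →
positive` globally; the Youden cutoff maximizes J = sens + spec − 1 over
observed thresholds (ties → higher sensitivity, then lower cutoff).
Confusion metrics are exact count ratios; zero denominators surface as
NaN flags. Hosmer–Lemeshow groups by equal-count deciles of predicted
probability (ties pushed to the lower bin, zero-expected groups merged),
`Σ(O−E)²/(E(1−E/n_g))` against χ² with g−2 df — sized for *fitted*
probabilities, which is how the suite validates it. Decision curves
report NB(pₜ) = TP/n − FP/n·pₜ/(1−pₜ) with treat-all and treat-none
references; pₜ ≥ 1 is excluded.

## Orchestration (`pipeline`)

`run_study` executes simulate → extract → split → train (clinical,
Rad-score, DLR-score) → evaluate with strict leakage guards: validation
patients never touch normalization, ICC, pruning, λ selection, the
clinical screen, or the cutoff (chosen on training by Youden).
The chronological split supports both the ratio rule (first ⌈0.7n⌉ by
date, ties by patient id) and a calendar-threshold mode for cohorts
whose sizes were fixed by a date cut rather than an exact ratio. All
randomness funnels through seeds recorded in the report, and a rerun of
the same configuration is byte-identical (the config hash excludes
output paths).

## Problem sizes used in the checks

The end-to-end acceptance study uses 60 phantoms at 32×48×48 voxels with
the full filter bank (≈1 s extraction per patient); recovery simulations
use 20 seeds of n=500, p=50 cohorts; the Hosmer–Lemeshow size check uses
200 replicates at n=1000; the power comparison and monotonicity checks
run at reduced cohort/filter scale with the same code paths. These sizes
give stable statistical verdicts while keeping the default suite quick.

## Known limitations

- Feature-count parity with any specific extractor release is a
  non-goal; the engine emits the feature families the published
  signatures use plus their standard companions (465 features at the
  default configuration).
- The stub embedder validates the contract and information flow, not
  transfer-learning performance; published DLR AUCs are properties of
  the hospital cohort and are not reproduction targets.
- The LBP-3D variant is simplified (see above) and should not be
  compared numerically against other implementations.
- Wald CIs (not profile likelihood) are used throughout, matching the
  OR ± CI presentation convention of the emulated analysis.
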