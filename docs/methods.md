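# Methods

This note documents the models, numerical conventions, and design choices
behind `deltarad`, and what the synthetic cohort does and does not emulate.

## Feature extraction

**Discretization.** Intensities are binned with a fixed bin width anchored
at the ROI minimum: `level(v) = clip(floor((v − min_ROI)/w) + 1, 1, L)`,
with `w = 0.3125` SUV and `L = 64` for PET, `w = 10` HU and `L = 400` for
CT. A zero-anchored variant is available by config. The ROI-minimum anchor
matches common radiomics-library behaviour; fixed bin width (rather than a
fixed bin count) keeps the intensity resolution comparable across lesions.
Entropy uses the same discretization, in bits (log base 2).

**First-order.** SUVmax/SUVmean (HUmax/HUmean on CT) over the mask; MTV in
ml from the voxel count and spacing; TLG = SUVmean × MTV. AUC-CSH
integrates the fraction of ROI volume above `t · SUVmax` over `t ∈ [0, 1]`
(trapezoid, 101 thresholds by default): 1 for perfectly uniform uptake,
smaller for heterogeneous uptake. Dmax labels 26-connected lesion
components and returns the largest centroid-to-centroid distance in mm,
with 0 for a single component — component centroids rather than extreme
voxels, the standard dissemination convention.

**GLRLM.** Runs of equal grey level are counted along the 13 unique 3D
directions and the per-direction matrices are summed before computing
grey-level non-uniformity `GLN = Σᵢ(Σⱼ r(i,j))²/Nr` and run-length
non-uniformity `RLN = Σⱼ(Σᵢ r(i,j))²/Nr`. Out-of-mask voxels break runs.
The production implementation enumerates runs by boolean shift algebra
(link arrays AND-ed under progressive shifts); the test suite re-derives
every value with a naive per-voxel walking oracle and requires agreement
to 1e-10.

**NGTDM.** For each ROI voxel with at least one in-mask neighbour in its
26-neighbourhood, the absolute difference between its level and its mean
neighbour level accumulates into `s_i`; `p_i` is the level's share of valid
voxels. Busyness, coarseness, complexity, contrast and strength follow the
Amadasun definitions with zero-denominator guards: coarseness returns 1e6
(also used as a cap) when `Σ pᵢsᵢ = 0`, strength and contrast return 0 on
homogeneous ROIs, busyness returns 0 when its denominator vanishes. These
bounded sentinels keep degenerate ROIs (e.g. single-voxel masks) in the
feature table instead of producing infinities.

## RIM shells

The mask is eroded one voxel at a time with the 6-connected (face)
structuring element — each peeled layer is then one voxel of face
thickness; 26-connectivity is available by config. Shells partition the
mask exactly. Per shell: min/mean/SD/max intensity, voxel count, volume,
intensity sum. Feature vectors use a fixed shell count (default 6) under
two indexings — outer-based (`RIM_*_k`, k = 0 the envelope) and core-based
(`RIMcore_*_k`, k = 0 the innermost shell). Core-based names keep
"innermost shell" comparable across lesions of different depth, which
matters because inner shells tend to carry the response signal. Lesions
with fewer shells than the fixed length yield missing values that are
mean-imputed downstream; deeper profiles are truncated. Sphere-shell
(concentric geometric) partitions are deliberately not implemented: for
irregular lesions such shells mix intra- and peritumoral tissue.

## Delta features and preprocessing

Absolute delta is `EoT − baseline`; relative delta divides by the baseline
value, with cells whose |baseline| falls below 1e-8 of the column scale
recorded as missing rather than clipped — avoiding fabricated huge ratios —
and mean-imputed later. Seven feature-set combinations are supported:
baseline, EoT, baseline+EoT, relative delta, absolute delta, and baseline
plus either delta. Z-scoring uses population SD with train-only fitting
when a fit partition is given; constant columns map to zero.

## Scanner effects and harmonization

Additive (mean-shift) effects are tested per feature with Welch's t-test —
unequal variances are assumed because heteroscedasticity is exactly what
the companion Bartlett test probes. Raw flags at α and Benjamini–Hochberg
flags are both reported; no correction is silently imposed.

Longitudinal ComBat variant: per feature, a joint least-squares fit of
intercept + time-point + subject dummies + scanner dummies estimates the
scanner location effect. The joint fit matters: a two-stage fit (subject
intercepts first, scanner effects from residuals) attenuates the scanner
coefficient by roughly half when subjects mix scanners across time points,
because per-subject intercepts absorb part of the shift. Location estimates
are standardized by the residual scale and shrunk across features with a
clipped moment estimator (pooled weights); multiplicative effects are
estimated from marginal, time-detrended per-scanner variances — per-subject
intercepts split each subject's noise evenly across its two scans, so model
residuals cannot see the variance ratio — and shrunk on the log scale.

Both adjustments sit behind significance gates (χ² over standardized
location estimates; Fisher-combined Bartlett p-values for scale, α = 0.05):
when no batch effect is detectable the table is returned unchanged. This
mirrors the practical workflow (harmonize only when tests fire), makes the
adjustment idempotent, and keeps the Kolmogorov–Smirnov before/after check
trivially non-significant on null data. The χ² gate treats features as
independent, an approximation that is conservative in the direction of
adjusting when real correlated shifts are present. Exactly two scanners are
supported — a deliberate scope restriction. Whether harmonized features
are propagated downstream is a config switch, not a default.

## ICARE

Each member model z-scores features, computes univariate discrimination
(`u` = ROC AUC against the binary label, or Harrell's c against censored
times), assigns weight `w = sign(u − 0.5)`, drops features with margin
`|u − 0.5| < Cmin`, greedily decorrelates survivors (descending margin,
dropping any feature with |r| > ρ to a kept one), retains a random subset
of at most F, and scores `risk(x) = mean(w_j z_j)`. Choices the published
description leaves open, fixed here: the margin metric is AUC/Harrell-c
(making classification and survival symmetric), filtering precedes the
random F-subsample, AUC ties count 0.5 (Mann–Whitney convention), and
hyperparameter search draws F ∈ {1..min(30, p)}, Cmin ∈ [0, 0.2],
ρ ∈ [0.3, 1.0] uniformly. Bagging fits each member on a bootstrap resample
(redrawn if a class vanishes) and aggregates by the median; tuning ranks
random hyperparameter sets by Monte Carlo CV, members draw from the top-B
sets, and B itself is chosen by an extra CV loop. All member seeds derive
from one generator, so ensembles are reproducible. Risk scores are
anti-concordant with survival time (higher risk = earlier progression).

## Classification protocol

Nested CV defaults follow the study protocol (10 outer folds × 5 repeats,
5 inner folds × 20 repeats, optional 15% stratified holdout); tests and the
acceptance script run reduced configurations (typically 5 × 1 outer,
3 × 1 inner, three selected features) as their chosen problem sizes. Per
outer-training fold: correlation filter (constants dropped, then greedy
|r| > 0.8 in column order) → SMOTE → z-score → sequential forward selection
scored by inner-CV F1 (ties break on the lowest column index) → final
model. KNN tunes k ∈ {3, 5, 7} in the inner loop; LDA runs without
shrinkage; RF uses 500 trees by default.

SMOTE interpolates synthetic minority samples between minority points and
their k nearest minority neighbours until classes balance. It is applied
*inside* each training fold by default; the literal balance-then-split
ordering is available as `smote_mode="before_split"` for comparison but
leaks test information into the synthetic samples and inflates metrics —
which is why the leak-free mode is the default, and why the test suite
carries a canary (a feature equal to the label on a subset of rows must not
lift test accuracy). Greedy SFS cannot discover jointly-predictive but
marginally-useless feature pairs (XOR structure); the suite asserts this
limitation on a constructed instance rather than hiding it.

Reported metrics: accuracy, F1, recall, precision, tie-aware ROC AUC, as
mean ± SD over all outer-fold × repeat evaluations (the SD convention is
stated because fold-wise and repeat-wise SDs differ); holdout metrics are
reported separately and never pooled.

## Survival and recurrence

Harrell's c treats pairs (i, j) as comparable when `t_i < t_j` with subject
i progressing, plus tied times where i progressed and j was censored; risk
ties count 0.5; no comparable pair yields NaN with a warning. The
implementation is O(n²) pair counting, checked exactly against an
independent exhaustive oracle.

Coxnet standardizes features, fits an elastic-net Cox path
(`alpha_min_ratio`, `n_alphas` configurable), and selects (α, l1_ratio) by
shuffled k-fold CV maximizing mean c-index; the reported c-index is the
cross-validated value at the selected pair, with nonzero coefficients from
a full-data refit. Feature selection front-ends (SFS, χ² on shifted
non-negative features, mutual information, random-forest importance,
LASSO-filter) rank features against the *binary* progression label — the
faithful reproduction of the protocol — even though selecting against the
survival outcome directly would be statistically preferable; both routes
are callable.

Recurrence regression standardizes features and target, grid-searches a
gradient-boosting regressor, and reports cross-validated R², MAE on the
standardized (dimensionless) scale — raw-scale MAE is also returned — and
MAPE excluding near-zero standardized targets (logged count).

## Synthetic cohort: what it emulates, and what it does not

Defaults are the study conditions: 31 subjects (both time points), ~20%
progression, two scanners with equal assignment probability per scan,
follow-up up to 60 months, censoring rate 0.3. Lesions are spheres with
radial uptake `peak(1 − (r/R)^g)` above a background of 1 SUV (peaks 8–20,
radii 8–20 mm, Gaussian noise SD 0.2 SUV); an irregularity knob perturbs
the radius directionally for irregular-shape code paths. CT is uniform
soft tissue (40 HU) with a +25 HU lesion offset and 10 HU noise. Treatment
multiplies lesion volume by a shrinkage factor (responders 0.02–0.15,
non-responders 0.4–0.9, 75% responders), scales peak uptake down, and
flattens the radial profile for responders (homogenization). The latent
response score is the noise-free relative change in TLG plus 0.5 × the
relative change in the intensity coefficient of variation; progression is
Bernoulli(logistic(2 + 4·score)) — the intercept set so the expected
progression rate is ≈17–22% — and TTP is Weibull(k = 1.5) with scale
40·exp(−2·score) months. These choices give the latent score a TTP
concordance of ≈0.70, the same order as published radiomics signatures.

Deliberate simplifications, hence limits on what passing tests show about
real data: no scanner point-spread or reconstruction modelling, no motion,
no multi-organ anatomy, no registration error (both time points share one
grid — registration is out of scope as masks are inputs); treatment
response is drawn *independently of the baseline scan*, so baseline-only
models are near chance by construction and the recurrence-volume
regression has essentially no recoverable signal on the image cohort (the
regressor itself is validated on a noiseless smooth-function recovery
instead). Real cohorts violate several of these — which is exactly why the
package tests parameter recovery on known ground truth rather than
claiming clinical performance.

## Numerical conventions

Population (ddof = 0) SDs in z-scoring and ICARE; sample SDs inside the
statistical tests that define them. All stochastic stages accept either a
seed or a `numpy` Generator; derived member/fold seeds are drawn below
2³¹. Degenerate inputs have defined behaviour throughout: empty masks
raise, constant columns z-score to 0 and are dropped by the correlation
filter, all-missing columns are dropped with a warning, zero survivors in
ICARE yield a constant-0 model with a warning, folds that lose a class are
skipped with a warning, and inner-CV candidates whose fit degenerates
(constant feature on a training split) score 0 for that fold.
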