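# Methods

`gradientshift` implements a gradient-based analysis of emotion-regulation
fMRI: task-evoked whole-brain activation maps are projected onto canonical
macroscale gradients of brain organization, the Regulate-minus-Look shifts
of those projections are related to behavioral regulatory success with
random-intercept mixed models, and the predictive value of the shifts is
assessed with cross-validated permutation inference. Everything runs
end-to-end on synthetic cohorts with known ground truth, so each stage is
testable without any imaging download.

## Gradient projection

Each subject contributes two unthresholded contrast volumes (Look > baseline,
Regulate > baseline). A common analysis mask is the intersection of voxels
that are finite **and nonzero** in every gradient map (zeros in gradient maps
mark out-of-support background; the gradients define the coordinate system)
with voxels that are finite in every activation map (zeros in unthresholded
contrast maps are valid data). Images are never resampled: grids and affines
must match exactly, and heterogeneous inputs are refused rather than silently
interpolated. Voxels are ordered by sorted C-order linear index so vectors
are reproducible.

The similarity of a contrast map with gradient k is the Pearson correlation
over mask voxels, Fisher z-transformed:

    r_ik(c) = corr(map_i(c), g_k),   z_ik(c) = arctanh(r),  c in {Look, Regulate}

|r| is clipped to 1 − 1e-12 before `arctanh` so that degenerate perfectly
correlated synthetic inputs yield a large finite z instead of overflowing.
The per-gradient shift is ΔG_ik = z_ik(Regulate) − z_ik(Look). Euclidean
reconfiguration distances (ED5 over all five gradients, ED3 over G1–G3) are
computed on the Fisher-z coordinates, consistent with the ΔG scores (the
z-vs-r choice is not determined by the source analyses; z was chosen for
internal consistency). Correlation rather than a raw dot product is used
throughout; the two agree up to normalization for zero-mean maps, and the
correlation form makes similarity invariant to positive rescaling of a
contrast map — an explicitly tested property.

## Behavioral indices

Ratings arrive on study-specific scales that differ in range and possibly
direction. Every computation first re-orients ratings so that **higher =
more negative affect** (declared `higher_is_more_positive` scales are
flipped as `min + max − rating`). Then

* regulatory success (raw) = mean oriented Look rating − mean oriented
  Regulate rating, so positive = effective down-regulation;
* emotional reactivity = mean oriented Look rating;
* success is z-scored within study (sample SD, n−1 denominator) before any
  cross-study model;
* subjects more than 3 sample SDs from the sample mean of the z-scored
  success are flagged as outliers in a single pass (mean/SD are not
  recomputed after exclusions).

## Mixed model

The main model is a linear mixed model with a random intercept per study:

    success_i = b0 + b1 ΔG1_i + … + b5 ΔG5_i + b6 reactivity_i
                + b7 age_i + b8 sex_i + u_study(i) + e_i

`u ~ N(0, σ_u²)`, `e ~ N(0, σ_e²)`. Study enters as a random intercept only
(no random slopes); a fixed-effect reading of the study term would not pool
across studies and is not implemented. Estimation profiles the likelihood
over the variance ratio λ = σ_u²/σ_e² (group-wise partial demeaning reduces
GLS to OLS for fixed λ; a grid scan plus golden-section search over log λ
finds the optimum, with the λ = 0 boundary checked explicitly). ML is the
default criterion so AIC ladders are valid; REML is available for
coefficient reporting. This specialized fitter exists because the
permutation analyses need ~10⁵–10⁶ refits; the test suite verifies its
estimates, likelihoods, standard errors and empirical-Bayes intercepts
against an independent general-purpose mixed-model implementation.

Reported per coefficient: estimate, SE, Wald t with residual degrees of
freedom n − p, 95% CI, p. AIC counts all estimated parameters including the
two variance components (k = p + 2). Both marginal R² (fixed-effect variance
over total) and conditional R² (fixed plus random over total) are emitted,
since "variance explained" for mixed models is ambiguous. Rows with missing
values are dropped with a logged count; a single-group sample falls back to
OLS with a logged warning. Covariates enter on their raw scales.

Variant models are thin wrappers changing outcome or predictors: the
Euclidean-distance model (ED5 or ED3 replacing the five shifts), the
daily-life affect model (experience-sampling mean as outcome), and the
questionnaire models (habitual reappraisal / suppression sums as outcomes).
The interaction ladder fits the main-effects model and then models
augmented with all gradient-shift interaction products up to order 2…5
(5 models), all by ML, and reports AIC per row; rows whose design exceeds
the sample size are flagged unestimable rather than fatal.

## Descriptive tests

Wilcoxon signed-rank tests compare condition-wise projections against zero
and Regulate vs Look per gradient. Zeros are dropped, ties receive
mid-ranks. For n ≤ 25 the exact null distribution of the signed-rank
statistic is built by dynamic programming over doubled ranks (exact even
with ties, which off-the-shelf exact routines refuse); two-sided
p = 2·min(P(W ≤ w), P(W ≥ w)), capped at 1. Above n = 25 a normal
approximation with continuity and tie corrections is used; the two branches
agree to < 0.01 at n = 20 in tests. Bonferroni adjustment uses the declared
family size (5 gradients × 3 samples = 15 for the paired family; twice that
for the two condition-wise families).

## Out-of-sample prediction

Leave-one-participant-out CV refits the full mixed model by ML without the
held-out subject and predicts them from the fixed effects plus the refit
intercept of their (still observed) study — the standard mixed-model
prediction contract. Accuracy is the Pearson correlation of observed and
predicted outcomes across subjects. Significance: each permutation shuffles
the outcome across all subjects (a within-study scope is available as a
flag) and reruns the **entire** cross-validation; this full-rerun reading is
the conservative interpretation of outcome-shuffling nulls.
p = (1 + #{null ≥ observed}) / (1 + n_perm), one-sided, so p = 0 is
impossible and p ≥ 1/(1 + n_perm) always. The documented default is 5,000
iterations; tests and the demo run 19–199 to stay at desk scale.
Cross-sample prediction fits on one sample and scores a disjoint one using
fixed effects only (unseen studies contribute zero random effect); its
permutation null shuffles the test outcomes against the fixed predictions.

## Region-wise analysis and t-maps

Per-region shifts restrict the projection/shift computation to each atlas
region's surviving voxels (regions with < 3 voxels or degenerate variance
propagate as missing, never as zero). One mixed model per region predicts
success from the region shift plus the controls; Benjamini–Hochberg FDR is
applied separately within the cortical and subcortical families.

The group-level covariate map regresses each voxel's Regulate-minus-Look
contrast on an intercept and a subject covariate (success or the Gradient-1
shift) by OLS, giving a t map with df = n − 2. Maps are thresholded at a
two-sided voxel p (default 0.001) and face-adjacent clusters above a minimum
extent are tabulated by sign. Random-field cluster-level FWE correction is
out of scope; outputs are labelled as voxel-level thresholding with cluster
extents.

## Decoding

The decoding engine correlates an input map with each map of a term set
over the mask and ranks terms by descending r (ties broken lexicographically;
exclusions applied case-insensitively, default exclusion set: stimulation,
method, cortex, gyrus). Real meta-analytic term maps are an optional
external directory with a (term, path) manifest; the package ships only the
engine plus seeded synthetic term sets with a 25-entry cognitive-term
vocabulary for naming.

## Synthetic cohorts — the stated world

`make_gradient_basis` orthonormalizes a seeded Gaussian matrix into K
zero-mean, unit-norm, mutually orthogonal maps (K < n_voxels required).
`simulate_cohort` then, per subject: draws Look loadings on each gradient
(`N(0.5, 0.1²)` by default), adds a target shift for Regulate
(`N(0.12, 0.12²)` on G1, `N(0.05, 0.12²)` elsewhere), composes activation
maps as loading mixtures of the gradients (scaled to unit per-voxel RMS so
similarities are independent of the voxel count) plus i.i.d. Gaussian voxel
noise (SD 1.0 contrast units, chosen to put typical similarities near
r ≈ 0.3), and computes the **realized** shifts by running the projection
module on the generated maps. Behavior is generated from the realized
shifts, not the latent ones — projection is a correlation, hence nonlinear
in the loadings, and conditioning on the realized values is what makes
parameter recovery exact in expectation:

    success_i = −0.9 + 3.0·ΔG1_i + 0.3·reactivity_i + u_study + e_i,
    u ~ N(0, 0.25²),  e ~ N(0, 0.5²)

Trial ratings are emitted per condition (`Look ~ N(reactivity, 0.8²)`,
`Regulate ~ N(reactivity − success, 0.8²)`, 30 trials each), mapped to the
study's scale orientation and clipped to its bounds; default means sit ≥ 2
SD from the bounds so clipping bias is negligible. The default world has
four studies in two sample halves (15 + 15 discovery-like on 1–9 and 0–8
scales, 12 + 8 replication-like on 1–5 reversed and 1–7 scales), exercising
scale-range heterogeneity and orientation flipping. Daily-life affect
prompts (31 per subject, 1–5 scale) are generated for the replication-like
half with mean `3.4 + 1.19·ΔG1 + N(0, 0.3²)`. Identical (config, seed)
pairs reproduce byte-identical cohorts.

What the generator does **not** emulate: spatial autocorrelation,
hemodynamics, anatomical plausibility, non-orthogonal empirical gradients,
rating drift or missingness. A green test therefore establishes the
statistical machinery (estimation, calibration, determinism), not realism
of the imaging model.

### Calibration-experiment configurations

The acceptance tests scale simulations to desk size without changing the
generative structure: recovery uses n = 600 subjects over a 1,000-voxel
basis; Wald-null calibration uses 400 cohorts of n = 200 with all
programmed effects zero; permutation calibration uses 200 cohorts of n = 30
with 99 permutations each. For the permutation null the cohorts additionally
set the study-intercept SD and the trial-rating SD to zero: shared trial
noise makes the measured reactivity covariate genuinely correlated with the
success score, and between-study intercepts make outcomes non-exchangeable
across studies — either would be a true signal, not a null, for an
unrestricted outcome-shuffling test.

## Numerical choices and edge cases

* r-clip 1 − 1e-12 before `arctanh`; sample-SD (n−1) convention everywhere.
* Mixed-model optimizer: log λ grid on [−12, 8] (21 points) + 40
  golden-section iterations + explicit λ = 0 comparison.
* Wilcoxon exact/approximate switch at n = 25.
* Decoding and projection correlation denominators of zero raise errors
  (zero-variance inputs) rather than returning NaN.
* Empty masks, misaligned grids, missing conditions, singular designs and
  constant covariates raise typed, named errors.

## Known limitations

* Wald t with df = n − p is a simple residual-df convention;
  Satterthwaite/Kenward–Roger corrections are not implemented (negligible at
  the cohort sizes targeted, noticeable below n ≈ 20).
* The permutation null reruns the full LOOCV; with the documented 5,000
  iterations at n ≈ 600 this is minutes of compute even with the fast
  fitter.
* Cluster reporting is descriptive; no cluster-level error control.
* The shipped 25-term vocabulary is a synthetic stand-in for a real
  meta-analytic term list; decoding real maps requires a user-provided term
  directory.
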