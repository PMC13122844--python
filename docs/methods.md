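# Methods

This document describes the statistical model implemented by `motorsig`, the
synthetic cohort generator that drives it, and the reasoning behind the
package's default parameters.

## Overview

The package models individualized functional phenotyping of amyotrophic
lateral sclerosis (ALS) in sensorimotor cortex from block-design task fMRI.
Five movement conditions (left hand LH, right hand RH, left foot LF, right
foot RF, tongue) are presented in 12 s blocks separated by 15 s rest, four
repetitions each. Three analysis strands operate on the localized
sensorimotor voxels:

1. **Dual-shared-space classification** — robust Shared Response Models
   (rSRM) are fitted separately to the ALS and control groups; a held-out
   subject's data, projected through *both* group spaces, feeds a linear
   support-vector classifier under leave-one-subject-out (LOSO)
   cross-validation.
2. **Connectivity mapping** — voxel-wise eigenvector centrality (ECM) and
   seed-based Pearson correlation maps, with patient-minus-matched-control
   contrasts aggregated by King's disease stage.
3. **Latent-variable clinical modelling** — partial least squares regression
   (PLSR, NIPALS) predicts clinical scores (ALSFRS-R, PUMNS) from voxel-wise
   connectivity or activation features, with leave-one-out (LOO)
   cross-validation, weight back-projection into voxel space, and
   region-wise weight statistics (repeated-measures ANOVA with
   Holm-corrected paired comparisons).

## Robust Shared Response Model

For subjects i = 1..N of one group with data X_i ∈ R^{V×T}, the rSRM solves

    min Σ_i ‖X_i − W_i R − S_i‖_F² + γ Σ_i ‖S_i‖₁
    s.t. W_iᵀ W_i = I_k

by block-coordinate descent:

- **W-update**: orthogonal Procrustes, W_i = U Vᵀ from the SVD of
  (X_i − S_i) Rᵀ.
- **R-update**: R = (1/N) Σ_i W_iᵀ (X_i − S_i).
- **S-update**: entrywise soft-thresholding of X_i − W_i R at γ/2.

**γ = 0 contract.** At γ = 0 soft-thresholding at threshold 0 is the
identity, which would let S absorb the entire residual and make the
objective degenerate. The implementation therefore skips the S-update when
γ = 0 (S ≡ 0), making the model coincide exactly with the plain
alternating-Procrustes SRM; the test suite verifies this against an
independently written reference implementation. When γ is not given it
defaults to a data-scaled value.

**Transfer and projection.** For a held-out subject, a basis is obtained by
Procrustes against the *frozen* group R (one soft-thresholding pass for the
subject's individual term in between); run-2 data are then projected as
z = Wᵀ x. Dual-space features concatenate the projections through the ALS
model and the control model (ALS half first, Fortran-order flattening),
giving a feature vector of length 2·k·T₂.

**Classification.** Linear SVM (C = 1). LOSO cross-validation refits both
group models per fold with the held-out subject excluded.

**Balanced training folds.** Holding one subject out leaves its own class
with one fewer training member. In high-dimensional, small-n settings this
biases a max-margin classifier toward the larger class and pushes
permuted-label (null) accuracy systematically *below* 0.5 (measured here:
~0.42–0.44 on a 12-subject cohort), an artifact loss re-weighting does not
remove. Since the chance level of the binary task is 0.5 by design,
`loso_classify` balances each training fold by dropping random subjects
(seeded per fold) from the larger class; the measured null then averages
0.50 while real-signal accuracy is unaffected. This behavior is
`balance_training=True` by default and can be disabled.

## Eigenvector centrality

For masked data with voxel correlation matrix r, the similarity matrix is
A = (r + 1)/2 ("shifted", default, guaranteeing non-negativity) or
A = max(r, 0) ("rectified"). ECM is the principal eigenvector of A,
computed by power iteration (tolerance 1e-10), normalized to unit Euclidean
norm; by Perron–Frobenius it is entrywise non-negative. A dense
eigendecomposition oracle backs the tests.

Because the ECM vector is unit-norm, centrality is *relative*: any gain in
one set of voxels must be compensated elsewhere. This matters when
interpreting group differences and is what makes the PLSR back-projection
experiments below sensitive to the relative sizes of the regions of
interest (ROIs).

## Seed connectivity and stage contrasts

Seed maps are Pearson correlations between the mean time course of a
spherical seed (default radius 5 voxels) and every masked voxel. The stage
contrast averages patient-minus-matched-control map differences within each
King's stage (1–3), keyed by seed region. The disease signature of interest
is an inverted-U profile: negative at stage 1, positive at stage 2,
negative at stage 3.

## PLSR

NIPALS with X-deflation; the first weight vector equals the dominant left
singular vector of X_cᵀY_c, and at full rank the fit coincides with
ordinary least squares (both verified against oracles). LOO
cross-validation reports per-fold MSE and the held-out subject's first two
latent coordinates. First-component weights are back-projected onto the
combined localizer mask, and region-wise mean absolute weights (hand, foot,
tongue) are compared with a one-way repeated-measures ANOVA,
F = MS_region / MS_(region×subject) with dof (r−1, (r−1)(n−1)), followed by
Holm-corrected paired t-tests.

## Synthetic cohort generator

No public data accompany the modelled study, so all quantitative behavior
is established on synthetic cohorts with known ground truth. Each
subject's data are

    data = baseline + W_i R_g + activation + S_i + noise

- `baseline` = 100 (arbitrary BOLD units; gives per cent signal change a
  meaningful denominator).
- `W_i R_g`: subject-specific orthonormal basis (V×k, k = 5) times a
  group-specific shared response — the signal the rSRM is designed to
  recover. ALS and control groups draw distinct R_g.
- `activation`: HRF-convolved boxcars locked to each condition's blocks,
  placed in that condition's ROI cluster (double-gamma HRF, peak ≈ 5 s).
- ROI-pair temporal couplings are shifted by `stage_connectivity_offsets`
  {1: −0.10, 2: +0.12, 3: −0.20}, the inverted-U profile.
- A per-patient severity latent scales connectivity changes through
  `severity_roi_weights` and generates the clinical scores: ALSFRS-R
  decreases and PUMNS increases with the latent, plus Gaussian noise of SD
  `clinical_noise_sd` (default 0.1).
- `S_i`: sparse individual term (default sparsity 0.05, amplitude 0.5).
- `noise`: white Gaussian scaled so that signal SD / noise SD = `snr`
  (default 3). `snr = inf` with `sparsity = 0` reproduces the stored
  noise-free signal exactly (tested).

**Default ROI layout.** Five disjoint clusters on a 16×16×4 grid at 1.5 mm
isotropic: LH and RH 60 voxels each, LF and RF 20 each, tongue 40 — 200
voxels in total. The hand fields are deliberately the largest, mirroring
the relative extents of the somatotopic representations in the motor
homunculus. The sizing also has a statistical role: ECM is unit-norm (see
above), so severity-driven centrality gains in the driver regions (foot,
tongue; weights {LH 0.2, RH 0.2, LF 0.8, RF 0.8, TONGUE 1.0}) are
compensated by anti-correlated decreases spread over the remaining voxels.
If the driver regions formed the majority of the mask, the per-voxel
compensation in the hand fields would exceed the per-voxel driver effect
and invert the apparent topography of the PLSR weights; with drivers in
the minority the generative topography survives the normalization.

**Design schedule.** One randomized block order per cohort (seeded), 20
events, 15 s lead-in and 15 s gaps: ~555 s ≈ 278 frames at TR = 2 s.
`n_timepoints` can truncate the series (used for speed in classification
experiments); connectivity/PLSR recovery experiments use the full-length
design because per-voxel correlation estimates at T = 120 are too noisy
for stable weight recovery.

**Chosen problem sizes.** Quantitative checks run at reduced size as a
package choice: chance-level calibration uses 12 subjects, V = 200,
T = 120, k = 5, snr = 2, 200 label permutations; PLSR weight-recovery
experiments use 40 patients (clinical noise is the pinned parameter, cohort
size is not); rSRM recovery uses cohorts where the shared response is the
only structured signal (activation, coupling and severity terms disabled)
at snr = 10.

## Preprocessing notes

- Band-pass: zero-phase Butterworth 0.01–0.1 Hz, order 4 (applied
  forward/backward). Infeasible bands or too-short series raise a typed
  error.
- Block synchronization permutes frames so condition blocks follow the
  canonical order (LH, RH, LF, RF, TONGUE), each block carrying its
  movement window plus the following rest. GLM localization must therefore
  run on data in acquisition order — its regressors are built from the
  schedule — while correlation-based measures (ECM, seed maps) are
  invariant to frame permutation.
- Per cent signal change uses block-minus-flanking-rest numerators and a
  *raw-series* rest baseline denominator by default, since filtering or
  z-scoring destroys the baseline level.

## GLM localizer

Per-voxel ordinary least squares on HRF-convolved condition regressors plus
intercept; t-maps per condition with dof = T − rank(design); all-zero
voxels get t = 0 with a warning, and no autocorrelation correction is
applied (block designs at TR = 2 s leave this second-order). Per-subject
masks take the top-k voxels by t-value (deterministic lexicographic
tie-break); group masks are the largest 26-connected component of the
intersection; the combined mask is the union across conditions. The
false-positive rate on pure-noise voxels is verified to sit at the nominal
α (5 ± 2% at α = 0.05).
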