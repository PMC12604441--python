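# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical decisions a maintainer should know about.

## The analysis in one paragraph

Knee-bone shape in a population of young adolescents is summarized by a
statistical shape model (SSM): after rigid groupwise alignment (no scaling
— size differences during growth are part of the signal), every bone
surface is re-expressed as P corresponding points; PCA of the stacked
3P-vectors yields a mean shape, orthonormal modes φ_k and eigenvalues λ_k.
A shape's score on mode k is reported in SD units, s_k = φ_kᵀ(x − x̄)/√λ_k,
so ±3 SD reconstructions x̄ ± 3√λ_k·φ_k bracket the population's variation.
Each mode's scores are regressed on one loading exposure at a time
(BMI-SDS, sports participation at 13, sports at 9&13 vs only at 13, active
days/week, active transport) with a Gaussian identity-link GEE clustered on
subject, adjusted for sex and age, using robust sandwich standard errors;
modes explaining ≥ 1% of total variance are tested against a Bonferroni
threshold 0.05/(number of included modes).

## Synthetic data: what it emulates, what it does not

The generator is the study-conditions definition, not a tuning knob.

* **Cohort** — per-subject covariates drawn to match the published
  participant characteristics: P(girl) = 0.52; age ~ N(14.1, 0.67²) y;
  BMI-SDS ~ N(0.43, 1.2²); P(sports at 13) = 0.70 and, conditional on it,
  P(also at 9) = 0.655; active days/week ~ round(N(5.3, 1.8²)) clipped to
  0–7; P(active transport) = 0.62. Every subject contributes a left and a
  right knee row. Optional missing-completely-at-random masks per covariate
  (off by default) mirror the per-variable missing counts of cohort tables.
* **Shapes** — x = x̄ + Σ_k s_k √λ_k φ_k + ε, ε ~ N(0, σ² I) per coordinate.
  True modes are smooth displacement fields (isotropic size, axis
  stretches, seeded low-order polynomial deformations) orthonormalized by
  QR, so "mode 1 ≈ size" emerges as in real bone populations. Scores are
  s = (effect · covariates) + √ρ·z_subject + √(1−ρ)·z_knee with z standard
  normal, giving unit marginal noise variance and exactly exchangeable
  within-subject correlation ρ. The default ρ = 0.8 is a placeholder — the
  empirical left–right shape correlation in adolescents is not published —
  and is an explicit config parameter.
* **Not emulated** — real anatomy beyond gross size/aspect (templates are
  an ellipsoid and a capsule-plus-two-condylar-blobs implicit surface),
  growth plates, segmentation error structure, scanner artifacts, informative
  missingness, and any nonlinearity in covariate–shape relationships.
  Passing tests therefore demonstrate correctness of the estimators under
  the stated generative model, not performance on clinical MRI.

## Segmentation fusion

The spatial prior is the arithmetic mean of deformed atlas one-hot labels.
The appearance component is any callable returning per-voxel class
probabilities. The two are pooled log-linearly,

    p_c(v) ∝ spatial_c(v) · appearance_c(v)^α,  α ∈ [0, 1],

renormalized per voxel; α = 0 reproduces the atlas prior exactly and α = 1
is the plain product rule. The power-weighted product is the standard
log-linear opinion pool and matches the "down-weighting the appearance
component by a power" description of the reference algorithm, whose exact
formula is not public; a weighted *sum* is the main alternative and is
deliberately not implemented to keep one documented semantics. Voxels where
every class has zero pooled mass fall back to background (counted and
logged). α is tuned by leave-one-out cross-validation over the atlases,
maximizing mean foreground Dice of the argmax segmentation against the
held-out reference; ties resolve toward smaller α (less appearance
influence). Dice of two empty masks is defined as 1.0. Argmax ties resolve
to the bone class (background last). Deformable registration and the
trained appearance classifier of the reference method are out of scope by
design; both are injection points (`registration=`, `classifier=`).

## Mesh pipeline

* **Marching cubes** runs on the Gaussian-smoothed class indicator
  (σ = 1 voxel default) rather than the raw binary grid: binary marching
  cubes overestimates a 10 mm sphere's area by ~9% (staircase bias), the
  anti-aliased indicator is accurate to ~1% in area and ~2% in volume at
  0.7 mm spacing. If smoothing would erase a thin object (peak below the
  iso level), the raw indicator is used instead. Volumes are zero-padded so
  border-touching surfaces close; face orientation is fixed so enclosed
  volume is positive. A single voxel becomes its dual octahedron with
  volume spacing³/6 — an intrinsic property of the algorithm worth knowing
  when voxel-level structures matter.
* **Mirroring** reflects right-side meshes across the sagittal plane
  through the bounding-box center (configurable), flipping face winding to
  keep normals outward; the operation is an involution. The anatomical
  left–right axis is assumed along x.
* **Loose bodies**: the component with most faces is kept (ties: larger
  enclosed volume). Meshes whose *second* component exceeds 10% of the
  faces are flagged for exclusion rather than silently filtered — the
  analog of excluding bipartite patellae — with the threshold configurable.
* **Smoothing/remeshing**: per round, edges longer than 4/3 of the target
  edge length (default: input median) are split, duplicates merged, then
  volume-preserving Laplacian smoothing (5 iterations) is applied; two
  rounds by default. The contract is behavioral — edge-length CV reduced,
  enclosed volume changed < 5%, watertightness preserved (violations raise)
  — rather than bit-compatibility with any particular remeshing filter
  dialect.
* **ICP** is rigid only (det R = +1, no scaling): moving vertices are
  matched to their closest points *on the reference surface* (KD-tree over
  triangle centroids, exact point–triangle projection), then a Kabsch fit
  is applied; the mean closest-point distance is non-increasing by
  construction (overshooting steps are rejected) and iteration stops when
  its decrease falls below 1e-4 mm or at 50 iterations. Initialization:
  centroid + principal axes with the best of the four proper sign flips.
  Collinear point sets are rejected.
* **Femoral cut**: after alignment (shaft along +y), vertices beyond 70 mm
  from the bounding-box bottom are sliced off and the cut is capped with a
  planar fan from the boundary-loop centroid, keeping the mesh closed; the
  operation is idempotent and a no-op (with a warning) on shorter meshes.
  Whether the reference analysis measured the cut before or after alignment
  is ambiguous; this package cuts after alignment, and the keep-length and
  axis are parameters.

## Shape model

Groupwise alignment iterates "rigid-fit every shape to the current mean,
re-average" from an order-independent initialization (average of centered
shapes), to mean movement < 1e-6 mm or 50 iterations. Correspondence is
one-shot closest-point from a template to every aligned surface; the
template is the medoid (minimum summed distance to all others) — a
deterministic, data-driven replacement for a manually chosen reference.
PCA uses raw mm coordinates (no size normalization), eigenvalues with the
N−1 convention, and a deterministic sign convention (largest-magnitude
loading of each mode positive).

Two properties of this classic construction deserve emphasis:

* **Correspondence attenuation.** Closest-point matching captures only the
  surface-normal component of a displacement field; tangential sliding is
  invisible to it. Fitted eigenvalues of tangentially-acting modes (e.g.
  stretches of a near-sphere) are therefore systematically smaller than the
  generative ones, and scores in fitted-SD units differ from generator-SD
  units by the same factor. Spectrum-recovery guarantees are stated for
  populations with known correspondence; the full pipeline recovers effect
  direction and significance.
* **Noise-dimension trade-off.** With isotropic residual noise σ, the
  top-K subspace error of PCA grows like √(3P·σ²/(N·λ_K)). At N = 200,
  σ = 0.05 mm and λ₃ = 1 mm², a P = 642 template implies ~9° of
  irreducible subspace error while P = 42 implies ~2.3°; recovery
  experiments therefore use the coarse 42-point template, which tests the
  estimator rather than the noise floor.

Distance maps report per-vertex distances between the ±3 SD
reconstructions and the mean, signed along the outward mean-surface normal
when the template faces are available.

## Association

One GEE per (mode, exposure): Gaussian family, identity link, clustered on
subject, exchangeable working correlation by default (independence
available) — the sandwich covariance makes the estimates valid either way.
CIs are β ± 1.96·SE and p-values use the normal reference; no small-sample
correction is applied. Sex is coded girl = 0 / boy = 1, sports9and13
compares "both 9 and 13" against the reference "only at 13" with
non-participants excluded from that fit, and complete-case deletion is per
(mode, exposure) fit with per-row N reported. Constant exposures and
rank-deficient designs raise with the offending column named. Emitted
tables round β/CI to 3 decimals and the threshold to 4, matching the
precision of published association tables.

## Problem sizes and runtimes

Defaults were chosen so the full test suite and the acceptance script each
run in minutes on a single CPU: pipeline demo 200 subjects (≈35 s),
spectrum recovery 10 replicates of 200 shapes at P = 42 (<1 s), GEE
calibration 1000 replicates of 500 subjects × 2 knees (≈55 s), geometry
checks on a 10 mm sphere at the scanner's 0.7 mm spacing. All stochastic
stages consume named seed streams derived from one top-level seed.

## Known limitations

* Correspondence is one-shot; no iterative re-correspondence after mean
  updates (an optional refinement is a natural extension).
* No deformable registration or learned appearance model ships; the fusion
  stage is exercised with identity/shift warps and oracle/uniform/toy
  intensity classifiers only, at phantom scale.
* The published segmentation accuracy (Dice 0.91 patella / 0.97 femur) is
  a property of non-deposited MRI data and is not a reproduction target.
* Reflections are confined to `mirror_to_left`; all other transforms are
  proper rigid. Chirality differences therefore survive alignment, which
  is intended.
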