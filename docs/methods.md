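# Methods

## Problem and model

`posturekit` classifies *which* seated balance task a person performs and
*how stable* they are while performing it, from two kinds of multivariate
time series: 3-D trajectories of skeletal joint centroids from a markerless
motion-capture camera (30 Hz, up to 25 joints), and the 2-D center-of-pressure
(COP) trace of a force plate under the seat (600 Hz).

The core representation is the **spatial covariance matrix** of a trial.
For a recording `X` (channels × frames), the descriptor is

    C = (1/Nt) (X − X̄)(X − X̄)ᵀ ,

with the per-channel mean removed, so the descriptor is independent of the
subject's resting posture and of sensor offsets, and its shape is independent
of trial duration.  Covariance matrices are symmetric positive-definite (SPD)
and are treated as points on the SPD manifold under the affine-invariant
metric

    δ_R(C₁, C₂) = sqrt( Σᵢ log² λᵢ ),   λᵢ eigenvalues of C₁⁻¹C₂ .

δ_R is unchanged by any common invertible channel transform `V` (C → VCVᵀ),
which absorbs camera pose, subject height, and body proportions — the
nuisance factors that otherwise dominate between-subject variation.

For classification, matrices are mapped into the tangent space at a
reference point `C_ref`:

    S = Log( C_ref^{−1/2} C C_ref^{−1/2} ) ,

vectorized by the row-major upper triangle with weight 1 on the diagonal and
√2 off it, so that ‖s‖₂ = δ_R(C, C_ref) exactly.  The reference is the
**log-Euclidean mean** Exp(mean(Log Cᵢ)) of the training covariances — a
fast, non-iterative surrogate for the Karcher mean.  Tangent vectors feed an
L2-penalized multinomial logistic regression.

Two classification problems share this pipeline:

* **Task** (6 classes): one model on all trials, regardless of condition.
* **Postural condition** (3 classes: both feet down / one foot up / both
  feet up): condition differences are nested inside much larger task
  differences, so one model is trained per task and a subject's *session*
  (their trials across tasks under one condition) is labeled by summing the
  six member probability vectors and taking the argmax; ties break toward
  the lowest condition index and are logged.

Evaluation is leave-one-subject-out (LOSO).  Every fitted component —
including the tangent reference — is recomputed per fold from training
subjects only; the reference is part of the feature map, and fitting it on
all data would leak test statistics into the features.  The hash-audit test
verifies that permuting a held-out subject's labels leaves that fold's
models bit-identical.

## Synthetic data generator

The generator emulates the statistical structure of a 12-subject × 6-task ×
3-condition seated balance study with simultaneous camera/force-plate
recording, so the entire pipeline is testable without any downloads.

* **Task structure.** Each task k has a 48×48 SPD template
  `C_k = B_k B_kᵀ + I` (16 upper-body joints × 3 axes), with `B_k` entries
  N(0, 1/48).  A draw is accepted only when all pairwise δ_R ≥
  `template_separation` (default 3.0; random draws at this dimension
  separate by ≈ 4.4, so retries are rare).
* **Condition effect.** A fixed random 6-dimensional "sway subspace"
  (projector `P = UUᵀ`) models the directions recruited by compensatory
  movements.  Condition c multiplies variance in that subspace by γ_c
  through `L L ᵀ = C_k^{1/2} D_c C_k^{1/2}`, `D_c = I + (γ_c − 1)P`.
  Defaults γ = (1.0, 1.5, 2.25), i.e. geometric spacing with ratio 1.5;
  `with_gamma(g)` builds (1, g, g²).  Because the effect is confined to a
  subspace, conditions are not separable by total variance alone.  The
  population distance between conditions c, c′ is exactly
  √6·|log γ_c − log γ_c′| (tested).
* **Subjects.** Each subject applies `V_s = (1 + ε) R_s`, a rotation of
  magnitude `subject_transform_scale` (default 0.1) times a scalar
  rescaling — body geometry and sensor placement.  A constant per-joint
  offset exercises the mean-removal and cleaning paths.
* **Dynamics.** Latent sources are AR(1) with φ = 0.95 and innovations
  scaled by √(1−φ²), so the stationary source covariance is the identity
  and the population covariance of a trial is exactly `V_s L Lᵀ V_sᵀ` —
  analytic targets for every test.
* **Force plate.** The COP pair is a linear read-out of the SpineMid
  lateral/depth channels, upsampled 30→600 Hz by linear interpolation, plus
  white noise of sd `cop_noise_sd` (default 0.2, signal units).
* **Seeding.** One master seed; structural draws (templates, subspace,
  subject transforms) and each (subject, task, condition) trial use
  disjoint `SeedSequence([seed, stream, ...])` streams, so any single trial
  is reproducible in isolation and datasets are bit-identical under a
  repeated seed.

What the generator does **not** model: realistic sway spectra, camera
depth noise, occlusion dropouts, or nonlinear trunk–COP coupling.  Passing
tests therefore demonstrate the pipeline's statistical and geometric
correctness under the assumed second-order structure, not clinical validity
on human recordings.

## Numerical choices

* Covariance uses the 1/Nt normalization (not 1/(Nt−1)).
* Default diagonal shrinkage 1e-6·(trace/N): enough to keep the matrix
  logarithm defined when channels are nearly constant (crossed-arm
  postures), small enough not to distort geometry.  Stronger shrinkage was
  evaluated and degrades condition classification — it biases the spectrum
  toward the identity and dilutes the subspace variance signal — so the
  minimal value is the default.  Note the shrinkage term is not affine-
  covariant; exact distance-invariance tests run at shrinkage 0.
* δ_R is computed via the symmetric generalized eigenproblem
  `C₂v = λC₁v` (Cholesky whitening), not the non-symmetric product
  `C₁⁻¹C₂`; matrix Log/Exp by eigendecomposition of the symmetrized
  argument, with symmetry violations above 1e-8 relative rejected rather
  than silently symmetrized.
* Logistic regression: lbfgs, C = 1.0, max 2000 iterations — deterministic,
  so refits on identical data reproduce weights exactly.
* Frame cleaning: interior dropout gaps are linearly interpolated per
  channel; frames missing in any channel at the edges are dropped; a channel
  missing more than half its frames (default) is a data-quality error.
* t-SNE perplexity defaults to 30, capped at (K−1)/3; embeddings are
  asserted only through label statistics (silhouette sign), never through
  coordinates.

## Design points that were genuinely open

* **Device agreement metric.** Per-trial Pearson r and RMSE between
  standardized position series (camera joint axis vs mapped COP axis), with
  camera lateral x ↔ COP X and camera depth z ↔ COP Y; the vertical axis has
  no COP counterpart.  Per-subject values average over conditions before the
  across-subject mean ± sd is reported.
* **Interpolation/decimation roundtrip.** Deriving the 600 Hz COP by linear
  interpolation and benchmarking via block-mean downsampling smooths an
  AR(1) signal: the noise-free correlation is ≈ √((1+φ)/2) ≈ 0.987 at
  φ = 0.95, not exactly 1.  Tests assert the analytic bound (≥ 0.98).
* **Generator convergence measure.** "Relative deviation" of an empirical
  covariance is normalized by the largest-magnitude analytic entry
  (elementwise ratios are unbounded where entries are near zero).  At
  φ = 0.95 the estimator's effective sample size is
  Nt(1−φ²)/(1+φ²) ≈ Nt/19.5, which bounds this deviation near 6–9% for a
  48-channel, 50 000-frame trial (iid sources: 1–2%).
* **Condition accuracy at default effect sizes.** With 300-frame trials at
  φ = 0.95 the per-trial covariance carries an effective ~15 samples for a
  48×48 estimate, and LOSO session-level condition accuracy at the default
  γ is ≈ 79–86% (mean ≈ 82% over seeds).  Diagnostics: with 3000-frame
  trials and no subject transform it reaches 100%, confirming the pipeline
  itself is not the limit; estimation noise at the default trial length is.
  Accuracy is strongly monotone in the effect size (≈ 36/82/90/98% for
  γ = 1/1.5/2/3).

## Known limitations

* The log-Euclidean reference is congruence-equivariant only under
  orthogonal/scale transforms; predictions are exactly invariant to a
  common rotation+rescaling of the channels but can shift slightly under
  general invertible maps (the Karcher mean would restore full
  equivariance, at iterative cost).
* The ensemble requires every task present at prediction time to have a
  trained member; tasks absent from training are skipped with a warning.
* KFP (2-channel) covariances carry little task information in the
  synthetic model, since the COP is read out from a single joint; synthetic
  KFP task accuracy is therefore far below what real force-plate data
  shows.
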