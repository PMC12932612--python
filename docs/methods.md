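# Methods

## Signal chain

Each recording is a T×3 matrix of head angular velocity (deg/s, sensor
frame, 128 Hz, gyroscope full scale ±2000 deg/s). Processing order:

1. **Edge trim.** `floor(0.05·T)` samples are removed at each end —
   recordings begin and end with start-up/wind-down artefacts. The fraction
   is configurable in `[0, 0.5)`.
2. **Low-pass filter.** A Butterworth low-pass, per-pass order 4, cutoff
   6 Hz, applied forward and backward (`scipy.signal.sosfiltfilt`, odd
   padding, pad length 3× the filter state length). Zero-phase filtering is
   the movement-analysis convention and keeps velocity and the derived
   acceleration phase-aligned; the price is that the effective magnitude
   response is the *squared* single-pass response — gain 0.5 rather than
   0.707 at the cutoff. The cutoff is not pre-warped for the dual pass, and
   this choice is visible in the analytic-gain tests. A causal
   implementation would shift the series by the group delay and change
   nothing else downstream.
3. **Velocity norm.** The elementwise Euclidean norm of the three filtered
   components. The norm is invariant to any fixed rotation of the sensor
   axes, which removes sensitivity to helmet/sensor alignment; it also
   discards direction (pitch vs yaw), which is out of scope here.
4. **Acceleration.** Central differences of the *filtered* velocity
   components ((x[i+1] − x[i−1])·fs/2 in the interior, one-sided at the
   ends — exact for linear signals, O(fs⁻²) otherwise), filtered again with
   the same low-pass, then the norm. A forward-difference scheme is
   available but not the default.

The whole chain is linear up to the norm and absolutely homogeneous after
it: scaling the input by a scales both norm series by a, and rotating the
input changes neither. Both properties are enforced as tests at 1e−9.

Degenerate inputs raise: recordings shorter than the filtfilt padding
(≈12 samples at order 4), trims leaving fewer than 2 samples, cutoffs at or
above Nyquist.

## Histogram modes, quartiles, interquartile area

The norm distributions are heavily skewed, so each participant × task series
is summarized by its **mode**: histogram bins are half-open
`[origin + k·w, origin + (k+1)·w)` with origin 0 and default widths 1 deg/s
(velocity) and 5 deg/s² (acceleration); the mode is the center of the most
populated bin, ties broken toward the lowest bin (deterministic). The widths
are a package default, not an empirically fixed constant, and every
mode-based guarantee is stated "within one bin". An all-zero series has its
whole mass in the lowest bin and therefore returns that bin's center (w/2),
the nearest representable value to zero under the bin-center convention.

Group-level task modes pool the *concatenated* samples of all participants
(not the mode of modes). Group quartiles Q1/Q3 are empirical 25th/75th
percentiles (linear-interpolation convention) of the pooled raw samples
across all tasks and participants — raw rather than binned, so they are
independent of the histogram spec. The interquartile **area**
(Q3ᵥ − Q1ᵥ)·(Q3ₐ − Q1ₐ)/1000 is reported in 10³·deg²/s³; the ÷1000 scaling
is the reading under which printed group quartiles of the reference cohorts
reproduce their printed areas (e.g. quartiles (13, 128)/(39, 358) give 5.98
against a published 5.97 computed from unrounded quartiles — a ≤0.1
rounding gap).

## Mixed model and cluster-robust inference

Responses are the per-participant × task modes, one model per measure
(deg/s and deg/s²):

    y_ij = α + α_i + β₁·group_g + β₂·task_t + β₃·(group × task) + ε_ij

* Treatment coding, references HS (group) and Walk (task); with 3 groups and
  11 tasks the fixed design has 1 + 2 + 10 + 20 = 33 columns, ordered
  intercept → group dummies → task dummies → interaction blocks per task.
* α_i ~ N(0, σ_α²) is a participant random intercept; ε_ij ~ N(0, σ_ε²).
  Estimation is REML (delegated to `statsmodels` MixedLM; cross-checked
  against an independent R/lme4 fit in the tests). Unbalanced designs
  (participants unable to perform a task) are handled as-is. If no
  participant repeats, the fit falls back to OLS with a warning. Exact
  zero-residual interpolation data yields zero variance components and a
  degenerate (zero) model covariance.
* **Sandwich covariance.** Working covariance Φ_c = σ̂_α²J + σ̂_ε²I per
  participant, weights W_c = Φ_c⁻¹, bread M = (Σ X_c′W_cX_c)⁻¹. CR0 is the
  plain Huber-White estimator; the default **CR2** rescales each cluster's
  residuals by the symmetric matrix A_c solving
  A_c(Φ_c − X_cMX_c′)A_c′ = Φ_c (computed via symmetric eigendecompositions
  with pseudo-inverse square roots), the generalization of the
  Bell-McCaffrey HC2 adjustment that makes the estimator exactly unbiased
  when the working model is correct. With singleton clusters and OLS weights
  CR0 reduces to HC0 and CR2 to HC2 — both enforced against explicit-formula
  oracles.
* **Satterthwaite df.** The robust variance of a coefficient is a quadratic
  form Σ_c(p_c′e_c)² in the data; under the working model its first two
  moments give df = tr(G)²/tr(G²) with G_cd = δ_cd·p_c′Φ_cp_c − r_c′Mr_d,
  r_c = X_c′p_c. This reproduces df = n − 1 exactly for the one-sample mean
  and approaches the normal limit as clusters grow. A model-based
  alternative (`vcov="model"`) pairs the REML GLS covariance with
  variance-component delta-method df (numerical REML Hessian), matching the
  C − 1 closed form on balanced one-way designs; CR2 remains the default
  because the robust covariance is what the published inference used.
* **Δ-percent.** Each coefficient is summarized as 100·(β − α)/α against its
  measure's reference-cell intercept, rounded to one decimal. This
  reconstruction reproduces all 64 published Δ cells exactly from the
  printed intercepts and estimates (frozen as a parametrized test).
* Correlations: Pearson r between velocity and acceleration modes per group;
  Spearman ρ (mid-ranks) between difficulty ratings scored easy=1, medium=2,
  difficult=3 and the modes, with "unable" excluded. The choice of Spearman
  for the subjective-objective comparison is a documented assumption.

Calibration of the whole inference stack is tested by simulation at the
study shape (19/20/20 participants × 11 tasks, σ_α = 3, σ_ε = 4): over 200
replicates, 95% CR2+Satterthwaite CIs cover the true coefficients within
92–98%, and under an all-null configuration the pooled rejection rate at
p < 0.05 stays within 3–7%.

## Synthetic cohort generator

The generator exists so that every downstream stage has a known answer.

* **Signal model.** Each axis is a sum of 6 random-phase sinusoids with
  frequencies uniform in 0.5–5 Hz — the band of natural head rotation —
  plus Gaussian noise high-passed above 10 Hz (default SD 1 deg/s) standing
  in for sensor noise; the analysis low-pass removes it (verified < 0.1
  deg/s residual in the interior). A small number of sinusoids keeps the
  norm distribution sharply peaked, as in real recordings, so the histogram
  mode is well localized; a large number would converge to a broad χ-like
  density whose binned argmax is unstable.
* **Calibration.** The chain is homogeneous, so one multiplicative constant
  sets the mode. Each recording's unit realization is processed once, then
  the constant is found by a one-dimensional fixed-point search on the
  *binned* mode (a ← a·target/mode(a·x), best iterate kept), putting the
  processed velocity-norm mode within one default bin of its target.
* **Cohort structure.** Defaults mirror the study: 19 BV / 20 UV / 20 HS,
  11 tasks, 30 s recordings at 128 Hz. Per-cell target modes are
  scale_g·target_t + α_i + ε with group scales 1.0 / 1.2 / 1.8 (the
  qualitative BV < UV < HS ordering; the HS scale places Walk near 15 deg/s,
  Stairs near 25 deg/s and UTurn near 60 deg/s, and the BV base near the
  published 8–13 deg/s band), participant SD 1.5 deg/s, cell SD 1 deg/s,
  floored at 1 deg/s. 17% of BV participants miss the Wood-beam task by
  default, mirroring the published "unable to perform" rate; difficulty
  ratings are drawn from per-group categorical tables (HS rates the Wood
  beam uniformly easy, BV finds the Wood beam and Inclined plane difficult)
  and missing cells are rated "unable".
* **Ground truth.** The truth table stores the generative cell value
  (`cell_mode_velocity`) and the *realized* modes of the emitted noisy
  recording (`true_mode_*`), computed at generation time with the default
  chain. End-to-end recovery (disk round-trip → processing → modes) is exact
  against the realized truth and within one bin of the generative value for
  ≳95% of cells; acceleration has no independent generative target, so only
  its realized mode is defined.
* **Reproducibility.** One master seed; per-recording streams derive from a
  CRC-32 hash of (participant, task), so regeneration is byte-identical and
  independent of iteration order.

**What the generator does not emulate.** Real recordings are nonstationary
(turns, stops, task phases), their velocity and acceleration modes decouple
(published Pearson r ≈ 0.12 between the two, versus ≈ 0.9 here, because a
single scale factor drives both in the synthetic signal), per-axis structure
is isotropic, task durations are uniform, and difficulty ratings are
independent of the kinematics. Passing tests therefore demonstrate that the
pipeline measures what it claims on signals with known structure — not that
the published cohort values are recovered from real data, which requires the
deposited recordings.

## Problem sizes used by tests and the acceptance script

The acceptance script runs the full default cohort (59 participants × ≤11
tasks, 30 s recordings). The test suite uses the same default cohort for
mode recovery, a 9-participant/4-task cohort for unit-level checks,
5-participants-per-group/4-task/10 s cohorts for the 100-replicate area
-ordering check, and 200 replicates at full study shape (responses simulated
directly at the mode level) for the coverage and null-rejection checks —
sizes chosen so each check's Monte-Carlo error is small relative to the band
it asserts.
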