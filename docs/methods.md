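# Methods

## Coordinate conventions and units

Skeleton frames live in camera space with axis 0 = mediolateral (ML),
axis 1 = superior–inferior (SI), axis 2 = anterior–posterior (AP, the depth
axis), in metres — the sensor-native unit. All sway outputs are in
millimetres; the single m→mm conversion happens when the CoM path is
emitted. The camera is assumed rear-facing, so its ML axis is mirrored
relative to the plate frame; the pipeline applies exactly one ML negation.
The plate frame has +ML = subject's left and +AP = anterior.

## The camera pipeline

1. **Mirror** — negate ML (an involution; applying the pipeline to an
   already-plate-frame recording would simply mirror the path's ML sign,
   which the downstream statistics are insensitive to in RMS terms).
2. **Align** — rigid whole-frame translation by minus the first frame's
   three-joint centroid (left hip, right hip, mid spine). We chose a
   whole-frame translation rather than per-joint re-referencing because it
   preserves intra-frame geometry exactly; since the sway statistic
   de-means both axes, any constant alignment anchor yields identical sway,
   so this choice is a documented convention, not a modelling claim.
3. **CoM per frame** — the three-joint centroid (primary) or a segmental
   total-body CoM (comparator). Short tracking dropouts of required joints
   are linearly interpolated in time before estimation; recordings with
   *persistent* dropouts (> 5% of frames for any core joint, configurable)
   are excluded upstream by the validity screen rather than repaired.
4. **Emit** — drop SI, convert to mm, keep native timestamps (30 Hz
   nominal; no resampling or filtering anywhere in the chain).

The segmental comparator uses a 14-segment table (head+neck, trunk, and
left/right upper arm, forearm, hand, thigh, shank, foot) with classic
cadaver-study mass fractions summing to 1 and proximal CoM locations;
segment CoMs are linear interpolations between the bounding joints. It is a
comparator only — distal joints are poorly tracked by depth cameras, which
is the motivation for the three-joint estimator.

## Recording validation

The screen mirrors the exclusion taxonomy of a paired camera/plate study:
`out_of_sync` (duration differs from the paired reference recording by
> 0.5 s), `malformed_skeleton` (core joint untracked in > 5% of frames),
`fall` and `harness_confusion` (annotation-only; the camera cannot detect
them from joint data), `over_recording` (duration > 1.5× the expected
trial length, i.e. one trial recorded over another), and `extra_recording`
(protocol bookkeeping: surplus third attempts). Thresholds are our
operationalisation of what was done by hand in practice and are exposed in
config. Rules are applied in the fixed precedence order listed, so every
excluded recording carries exactly one reason. The verdict depends only on
durations and tracking states, hence is invariant to uniform time shifts.
The default expected trial length is 20 s (a standard SOT trial).

## The force-plate model

The plate comparator treats the body as a rigid rod pivoting at the ankle
with the CoM at `c = 0.5527 × stature`. The CoF is corrected for a modelled
constant anterior lean of −2.3° (AP axis only — the lean is anterior), the
sway angle is `arctan` of the corrected CoF over `c`, and the CoM excursion
is `c·tan(θ)`. Algebraically the tan/arctan pair cancels, making the map
affine; we keep the angle form because the rigid-rod picture (and its
|θ| < 90° domain) is the model's substance. Whether a real plate applies
the lean per sample or as a calibration offset is immaterial here: the sway
statistic de-means, so any constant-offset convention produces identical
sway — this is asserted by test. No filtering is applied to the 100 Hz
trace. `com_to_cof` is the exact inverse and is what the simulator uses;
the round-trip is identity to < 1e-9 mm.

## Sway statistics

`RD_i = √((ML_i−ML̄)² + (AP_i−AP̄)²)`, `swayRMS = √(Σ RD²/N)` — population
(1/N) normalisation, forced by the definition, equivalently
`√(popvar(ML) + popvar(AP))`. Each channel is summarised at its native rate
(30 vs 100 Hz). Extras (path length, mean velocity, 95% ellipse area) are
available behind a flag but outside the core surface.

## Agreement statistics

Differences are A − B with A the plate channel and B the camera, so a
positive bias means the plate reads higher. LOA = bias ± 1.96·SD (the
multiplier that reproduces published two-SD limits at two decimals); CI of
the bias uses `t_{0.975,n−1}·SD/√n`; CIs of the LOA use the classical
approximation `var(LOA) ≈ 3·SD²/n` with the same t quantile (the convention
of standard method-comparison software; a normal 1.96 quantile differs
negligibly at the n involved). By default every record enters individually
(no averaging over repeats); `average_repeats` collapses to subject means
first, since the effective n of published significance tests is sometimes
ambiguous — both modes are provided. Repeatability uses paired repeats:
`SD_w = √(Σ_j d_j²/(2m))` over m subjects, `CR = 1.96·√2·SD_w` (the ratio
2.7718… is enforced as an invariant). Zero-variance differences are flagged
degenerate: LOA collapse to the bias and the t statistic is undefined
rather than fabricated. Display rounding is 2 dp, half away from zero.
Normality is screened with the D'Agostino–Pearson omnibus and Shapiro–Wilk
tests (skipped below n = 8, where the omnibus test is invalid); a Wilcoxon
signed-rank test accompanies the t-test as the nonparametric cross-check.

## The synthetic study

The generator replaces unavailable human recordings; it defines the
conditions every end-to-end test runs under.

**Sway process.** Ground-truth CoM motion is a stationary Ornstein–
Uhlenbeck process, independent per axis, sampled *exactly* (AR(1) with
coefficient `e^(−θΔt)`, stationary start) on a 300 Hz base grid and
decimated to 30 and 100 Hz so both instruments observe one movement. The
per-axis SD is `target/√2` so the stationary resultant RMS equals the
condition target. Targets (a: 2.9, b: 4.2, c: 4.0, d: 5.8, e: 17.1,
f: 15.3 mm) sit at the scale of reported cohort means for the six SOT
conditions; bandwidths rise from 0.3 Hz (quiet stance) to 0.7 Hz
(support-surface perturbation), reflecting the slow drift of quiet sway
versus the brisker corrections under perturbation. An OU process was chosen
because it is stationary, bandwidth-controllable and has closed-form
variance — which the calibration below exploits; real sway is neither
Gaussian nor single-timescale, so passing tests demonstrate estimator
correctness and calibration, not biological fidelity.

**Skeleton rendering.** A template standing body (joint positions as
fractions of stature, standard proportions: ankle 3.9%, knee 28.5%, hip
53.0%, shoulder 81.8%) is scaled to the subject's height. A fraction
`1 − λ` of the CoM displacement translates the whole body (ankle strategy);
the remainder is carried by the trunk joints alone, tripled because only
the mid spine of the three centroid joints rides with the trunk — so the
centroid follows the ground truth exactly for every λ. λ rises with
condition difficulty (0 for quiet stance to 0.5 under perturbation),
mimicking the ankle-to-hip strategy shift; it is a kinematic caricature,
not a biomechanical model. The result is mirrored into the rear-camera
frame (constant 2.5 m depth offset) and per-joint Gaussian noise (default
SD 2 mm per axis) is added. Subjects are drawn at height 172 ± 11 cm,
mass 75.1 ± 14.2 kg (clipped to plausible ranges).

**Plate rendering.** The exact pendulum inverse plus white noise (default
SD 0.5 mm), static-lean offset included.

**Bias injection, calibrated on the measured scale.** White measurement
noise inflates measured RMS (camera: `2σ_j²/3` resultant variance; plate:
`2σ_c²`), and a finite window shrinks the empirical variance of a
correlated process by a computable factor
`κ = 1 − [n + 2Σ(n−k)φ^k]/n²`. Both effects are exact in expectation of
the squared RMS, so the expected measured RMS of each channel is known in
closed form. The generator inverts this to find the camera-channel
amplitude scale realising a requested additive/multiplicative
between-method bias *as measured* — with zero requested bias the channels
agree in expectation despite unequal noise (empirical residual < 0.01 mm at
n = 300/condition). The remaining approximation is the Jensen gap between
`E[√X]` and `√E[X]`, below 1% at these window lengths and largely common to
both channels. A request below the camera noise floor raises an error
rather than silently clipping.

**Determinism.** One master seed is stream-split (`SeedSequence.spawn`) per
trial and per channel; any subset of a study is reproducible, and the CLI's
`simulate` is byte-identical across runs with the same seed.

**Delta-method repeatability.** When repeats share one ground-truth
trajectory (`share_truth_across_repeats`), the repeat-difference variance
is noise-driven: per axis `var ≈ (8Vσ² + 4σ⁴)/n`, propagated through the
square root. The predicted within-subject SD matches simulation within
~10%; tests assert 30%.

## Problem sizes and tolerances

Default trials are 20 s (600 camera frames, 2000 plate samples). The
end-to-end recovery checks use 50 subjects × 2 repeats (100 paired records
per condition) and assert recovery within 3 standard errors; t-test
calibration uses 2000 null replicates at n = 30 against a 3.5–6.5% band;
the condition-ordering check takes medians over 50 seeded studies. The
noise-free pipeline identity is asserted at 1e-6 mm (it achieves ~1e-13;
the slack absorbs platform variation), the pendulum round-trip and the
sway/variance identity at 1e-9 mm. Noisy single-trial sway recovery within
5% is exercised at a perturbed-condition amplitude (17 mm), where the
joint-noise inflation (~0.5%) is far inside the band; at quiet-stance
amplitude (3 mm) the same default noise inflates RMS by ~14%, which is
exactly the effect the measured-scale calibration above accounts for.

## Known limitations

- The simulator does not model depth-camera artefacts (per-joint bias,
  occlusion, soft-tissue wobble) or support-surface rotation mechanics;
  joint noise is white and isotropic, whereas real tracking error is
  autocorrelated and anisotropic.
- The hip-strategy mix moves the trunk without conserving whole-body
  momentum; it exists to exercise the pipeline under articulated motion,
  not to predict hip-strategy sway.
- The three-joint estimator and the pendulum model disagree systematically
  on real perturbed stance (that disagreement is the scientific question
  the analysis surface serves); the simulator reproduces such disagreement
  only when a bias is injected.
- Repeatability assumes exactly paired repeats; subjects with a single
  usable repeat are skipped, and more than two repeats contribute only
  their first two.
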