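# Methods

## Task and device model

The task is a center-out reach on a tablet: the participant tilts the device
to steer a cursor from a start circle (9 mm radius) to a target (4.5 mm
radius) at 50 mm distance, holding the start for 1 s and reaching within a
2 s window. Tilt is read from the accelerometer at 200 Hz and mapped to a
cursor position through a per-axis exponential low-pass filter with retain
0.95 and gain 0.05; `arcsin` of the accelerometer component is taken in
degrees so that the published offsets (o_x = 0, o_y = −30) are commensurate
with tilt angles. The filtered tilt vector is then rotated by the trial's
visuomotor rotation p_t; angles are clockwise-positive on screen, which
makes the clockwise block's rotations non-negative — the sign convention
the outlier-exclusion rule presumes.

Two offset conventions are implemented. `per_step` is the recursion exactly
as published, `p ← 0.95·p + 0.05·arcsin(a) − o`: its fixed point is
`arcsin(a) − o/gain`, which for o_y = −30 sits 600° off screen, so it is
retained for fidelity tests only. The default `set_point` mode applies the
offset inside the gain, `p ← 0.95·p + 0.05·(arcsin(a) − o)`, whose fixed
point `arcsin(a) − o` means a resting tilt of ~30° toward the user centers
the cursor — the physically sensible reading. The filter is a contraction
with factor 0.95 per sample, so a constant tilt θ is approached
geometrically with error θ·0.95ⁿ after n samples (about 2×10⁻⁷·θ at
n = 300).

Display gain is 1 mm of cursor travel per degree of filtered tilt. The gain
and the 50 mm target distance are configurable; with a ±15° rotation the
reach stays well inside the representable tilt range.

## Perturbation schedule

Each 40-trial block ramps the rotation by 1°/trial to a 15° maximum and
back to zero by trial 30, with trials 31–40 unperturbed:
|p_t| = t for t = 1..15, 30 − t for t = 16..30, 0 for t = 31..40. The
clockwise block is positive, the counterclockwise block its negation, and
block order is counterbalanced across participants. This symmetric triangle
is one consistent reading of "1°/trial, 15° max, 40-trial blocks"; the ramp
shape is configurable in principle but every numeric constant in the test
suite (block sum 225, fragment norm² 2051, window means) is derived from
this triangle.

## Trial scoring

Velocities are central differences of the display cursor at 200 Hz.
Movement onset is the first frame where y-velocity exceeds the trial's mean
plus 2.5 SD, both computed over the whole trial — the log contract carries
no separate pre-go baseline, so "per trial" is read as all frames. The
movement angle is the signed clockwise angle between the target line and
the velocity vector at the frame of peak y-velocity (search restricted to
frames at or after onset). The adaptation effect is `p_t − angle`, so
curves start near zero and rise toward the schedule under adaptation.
Movement time is onset-to-peak duration: the published group values
(51–109 ms) are only consistent with that reading, not with onset-to-target
time. Trajectory error defaults to the mean absolute lateral deviation from
the start x over onset-to-end frames (positive millimetres); the literal
signed mean and the squared variant are selectable because the two published
descriptions of this quantity disagree, and neither is privileged here.

Outlier trials are excluded when the effect exceeds `c + p_t` (for
p_t ≥ 0) or falls below `−c + p_t` (p_t < 0), with c = 15 by default; the
rule is deliberately one-sided per branch, as published. CW and sign-flipped
CCW effects are averaged trial-by-trial; when exactly one block's trial is
excluded the other substitutes alone (tagged `cw_only`/`ccw_only`), and
only when both are excluded is the entry missing — in which case the
decomposition refuses to run rather than impute, since the averaging scheme
is predicated on that situation not occurring.

## Decomposition

The curve fragment (x_9 … x_32), optionally shifted by an integer lag
Δ ∈ [0, 8], is compared with the schedule fragment (p_9 … p_32): the lag
minimizing the mean squared error (exhaustive search, ties toward the
smaller lag) is the temporal delay; amplitude is the norm ratio; phase is
the arccosine similarity (cosine clamped to [−1, 1] before arccos); RMSE is
the root mean squared residual at the best lag. The upper delay bound 8 is
forced by x_{32+Δ} having to exist within 40 trials. All file formats use
1-based trial numbers matching the x_1..x_40 convention.

Two intrinsic properties of this estimator are worth knowing. First, the
algebraic identity 24·RMSE² = |x|² + |p|² − 2·x·p ties the four outputs
together; in particular a noiseless proportional response with amplitude A
and phase 0 necessarily has RMSE = (1−A)·|p|/√24 (≈ 2.31° at A = 0.75) —
RMSE is small only when the response is *both* aligned and near-unity in
gain. Second, the lag search is biased at low amplitude: for a delayed-gain
response with gain a on this triangle, the margin between the true lag and
one lag earlier is 24·ΔMSE = 22a² − 42a(1−a), which crosses zero at
a = 42/64 ≈ 0.656 — below that the minimizer sits one trial early even
without noise, and near it the per-subject delay estimate is noise-
sensitive. The cohort presets (0.72–0.91) sit above the threshold, but
per-subject delay estimates at amplitude ≈ 0.72 with trial noise 1.5° are
correct only ~60% of the time; group-level (modal) delays are accordingly
reported alongside means.

## Group statistics

Per-trial two-sided one-sample t-tests against zero locate the adaptation
window; correction across the 40 tests is Bonferroni by default (Holm and
uncorrected available) — the correction used for the published window is
unspecified, and Bonferroni is the conservative choice. Significance is
`corrected p ≤ alpha`; the window is the longest contiguous significant
run, with isolated significant trials reported but not widening it.
Group comparisons are one-way fixed-effects ANOVA (scipy) followed by Tukey
HSD via the studentized-range distribution. Two-sample t-tests default to
pooled variance — the convention that reproduces the published demographic
p-values from their rounded summaries (0.1138 for age; Welch gives ≈0.116)
— with Welch available by flag, and run identically from raw samples or
summary statistics. Correlations report Pearson r and Spearman rho with
t-distribution p-values. Movement times are z-scored within group (sample
SD, ddof = 1) before pooling, so group-level speed differences cannot
masquerade as a speed–amplitude association.

## Synthetic cohort generator

The generator defines the study conditions for all closed-loop tests; real
cohort data are not redistributable, so recovery of generating parameters —
not reproduction of the original group means — is the validation target.

Each subject is a **delayed-gain adapter**: on block trial t the
compensated angle is e*_t = A_true·p_{t−Δtrue} + N(0, σ²), with the delay
applied within block (p at non-positive indices is zero) and σ = 1.5° by
default. A state-space learner is deliberately not used: it is known to be
a poor description of adaptation to a rising-and-vanishing schedule, and
the delayed-gain law is exactly identifiable by the decomposition above,
which is what the recovery tests require. Group presets (amplitude
0.91/0.75/0.72; delay 3/4/5 trials; movement time 109/96/51 ms with
between-trial SDs from the reported standard errors × √18) follow the
published cohort summaries as *generator settings*, not as reproduction
claims.

Within a trial the subject holds the start for 1 s, reaches with a
minimum-jerk profile along a tilt-space heading rotated −e*_t from the
target line (so the displayed angle at peak velocity is p_t − e*_t and
scoring recovers e*_t exactly), then smoothly corrects `feedback_gain`
(default 0.8) of the remaining display error with a second minimum-jerk
displacement spanning the rest of the 2 s window. The smooth correction
matters: a proportional step correction has a velocity discontinuity that
can exceed the reach's peak velocity on large-aim-error trials and corrupt
the peak-velocity measurement. The accelerometer channels are the analytic
inverse of the device filter, so running the device model on a generated
log reproduces the stored cursor to numerical precision (the round-trip is
tested at 10⁻⁶).

The reach duration is drawn from the preset movement time times 4.5,
bounded to [0.18 s, 0.9 s]: the lower bound keeps the per-frame tilt change
representable by the arcsine after division by the filter gain; the upper
bound keeps the reach a small enough fraction of the trial that the
whole-trial mean + 2.5 SD onset threshold still crosses the velocity bell
(a closed-form property of the min-jerk profile: crossing fails once the
reach exceeds roughly a third of the trial). The ×4.5 scale places the
*detected* onset-to-peak times near the preset group means; detected
movement time tracks the preset proportionally rather than exactly, which
is sufficient for the ordinal group comparisons it feeds.

Outlier trials (rate 0.04/trial) encode an aim error placed uniformly
20–40° beyond the exclusion bound of their trial's rotation-sign branch, so
the printed rule catches them by construction at c = 15 and still at
c = 20. CW and CCW outlier positions are drawn disjointly within a subject:
coincident outliers would leave a missing curve entry and abort the
decomposition, a situation the emulated cohorts did not exhibit.
Demographics are independent per-group Gaussian draws clipped and rounded
to their scales (MMSE integer in [23, 30] per the inclusion criterion,
Hoehn–Yahr on a half-point scale in [1, 5], UPDRS integer ≥ 0); no
within-subject correlation among clinical scores is modelled, matching the
null associations the generator is meant to emulate.

What passing closed-loop tests does **not** show: the generator has no
biomechanical arm/wrist model, no savings or inter-block transfer, no
reward or vibration feedback, no frame-level sensor noise, and its
trial-to-trial variability is white — so recovery results certify the
analysis code, not the behaviour of real participants.

## Numerical and design choices

- Seeds: every stochastic component takes a seed or `numpy` SeedSequence;
  cohorts spawn independent child seeds per subject, so runs are
  reproducible bit-for-bit and subjects are order-independent.
- Ties in the delay search break toward the smaller lag (parsimony).
- The arccos argument is clamped to [−1, 1]; rotation matrices are applied
  in double precision (round-trip error < 10⁻⁹).
- Degenerate trials (zero-variance velocity, no threshold crossing, zero
  velocity at peak) are flagged excluded with a reason rather than
  crashing a whole session; degenerate statistical inputs (zero-variance
  groups, empty windows) raise.
- Problem sizes in the test suite and acceptance script (18 subjects per
  recovery cell, 1000 random curves for the oracle checks, 54-subject
  cohorts for the group analyses) match the emulated study's scale.

## Known limitations

- The triangle is one reading of the published schedule description; a
  plateaued ramp would change the fragment constants.
- The delay estimator's low-amplitude bias (above) is a property of the
  published decomposition, not of this implementation; delay comparisons
  between groups of very different amplitude should be interpreted with
  that in mind.
- Absolute trajectory-error magnitudes depend on the unpublished display
  gain and on which of the three TE definitions is chosen; only ordinal
  group comparisons are meaningful.
- The pipeline analyses complete sessions (40 aligned trials per block);
  partially recorded sessions are rejected at scoring time.
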