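# Methods

`liftkin` analyses manual material-handling (MMH) trials — lifting (LL) and
releasing (RL) a small load — recorded by eight body-worn orientation sensors
(sternum, pelvis, both thighs, shanks and feet) sampled at 40 Hz, and
classifies each trial as *squat* (correct: trunk near upright, knees deeply
flexed) or *stoop* (incorrect: knees near extension, trunk fully bent).
Because no public recordings of this protocol exist, the package ships a
forward-kinematic simulator that emulates the full study design; every
downstream stage is exercised against simulated ground truth.

## Coordinate conventions

World frame: `x` medio-lateral, `y` antero-posterior, `z` vertical (up); the
sagittal plane is y–z. Quaternions are Hamilton, scalar-first, world←sensor.
Sagittal joint angles are rotations about the medio-lateral axis with flexion
(lumbosacral, hip, knee) and ankle dorsiflexion positive. The sign of the
rotation is fixed once, such that positive lumbosacral flexion produces a
positive antero-posterior component of the pelvis–trunk displacement vector;
every other joint sign (the table in `frames.py`) follows from requiring a
physically sensible chain (sitting: thigh pitch +90°, shank pitch 0°). All
internal math uses rotation matrices.

## Biomechanical model

**Filtering.** Orientation streams are low-pass filtered at 10 Hz (second-order
Butterworth magnitude). Because the analysis is offline, filtering is
zero-phase: the default implementation multiplies the reflect-padded spectrum
by the exact analog magnitude `1/sqrt(1+(f/fc)^4)`, which preserves RoM timing
(no phase distortion) and matches the analog response at every frequency —
a recursive bilinear design warps visibly once signal content approaches
Nyquist. A conventional forward–backward recursive variant
(`method="filtfilt"`) is available. Filtering is applied to rotation-vector
increments referenced to the first sample (never to raw quaternion
components), keeping the representation away from the ±180° branch cut
regardless of sensor mounting.

**Functional calibration.** Two five-second static captures. Standing fixes
each segment's vertical axis (gravity expressed in the sensor frame). For the
pelvis and thighs, the standing→sitting relative rotation occurs about the
medio-lateral axis (hip flexion/pelvic tilt), so its rotation axis — projected
orthogonal to the vertical — fixes x; trunk, shanks and feet barely rotate
when sitting down and inherit their anterior axis from the standing heading.
The result is an orthonormal constant segment←sensor rotation per segment.
A capture with more than ~3° of motion is rejected; a recovered map deviating
by more than 20° from the nominal mounting (e.g. a tilted "standing" pose)
raises a warning flag.

**Joint angles.** World←segment poses are `(world←sensor)∘(segment←sensor)⁻¹`.
Each joint angle is the first angle of the medio-lateral-axis-first Euler
decomposition of the relative rotation `R_parentᵀ·R_child`, signed per the
convention table; pure sagittal rotations are recovered exactly and the result
is invariant under a common world rotation of all poses.

**Pelvis–trunk displacement.** With the trunk origin `o = [0, 0, l_trk]ᵀ` in
the pelvis frame (`l_trk` = anthropometric trunk length, mm) and `R` the
pelvis→trunk rotation, the homogeneous transform `T = [R o; 0 1]` has inverse
carrying `−Rᵀo`; the displacement vector is

    PT = o − (−Rᵀ o) = (I + Rᵀ) o,

reported as AP = y, ML = x, V = z of the pelvis frame, degree-1 homogeneous in
`l_trk`. Raw values are reported; features use excursion ranges, which cancel
the constant `2·l_trk` neutral-pose offset, so whether a neutral offset is
subtracted first is immaterial downstream.

## Simulator

A planar seven-segment chain is driven by flexion-positive joint waveforms
through one descent–ascent cycle: a raised cosine (half-cycle down, half up),
0→1→0, with the peak at the descent fraction (0.5 for squat; 0.55 for stoop,
whose ascent is performed faster). Trial timing (4 s movement, 0.5 s
lead-in/out) is a simulator choice — the protocol's speed was self-selected
and no durations are published. Segment pitches follow the joint chain
(`trunk = pelvis + lumbosacral`, `thigh = pelvis + hip`,
`shank = thigh − knee`, `foot = shank − ankle`); the trunk additionally sways
medio-laterally (rotation about y) with a small load-scaled amplitude.

Condition-level targets (per task × posture; mean ± between-subject SD at the
1 kg load) are the simulator's defaults: e.g. LL squat hip 99.4 ± 10.7°, knee
102.1 ± 16.8°, lumbosacral 36.7 ± 12.4°, ankle 27.6 ± 7.9°; LL stoop knee
29.6 ± 20.8°, lumbosacral 52.5 ± 10.0°. Load increases hip excursion by
+1.2°/kg and ML sway mostly in the stoop posture (squatters hardly change),
reproducing the qualitative load ordering, not exact per-load means (the
observed spacing is not linear in kg). Subjects carry a per-parameter "trait":
draws are correlated across conditions (ρ = 0.8; 0.97 for ML sway, an
individual style nearly invariant across conditions — that is what makes the
small ML posture contrast detectable in a paired design while leaving each
condition's marginal distribution untouched). Within-subject repetition
jitter is 3° (0.8° for ML sway) and independent left/right jitter 1.5°; the
trunk-pitch targets (squat ≈ 50°, stoop ≈ 95°) are simulator choices that
close the chain.

Sensors: per-segment nominal mounting rotations (how an IMU case sits on the
body), a constant per-subject random misalignment (3° SD per axis; the
quantity functional calibration must recover), and small-angle white
rotation-vector noise (0.3° SD, smoothed at 10 Hz like the sensors' internal
filtering). Trunk length is drawn N(500, 40) mm clipped to 400–600 mm.

What the simulator does **not** emulate: soft-tissue artefact, magnetometer
disturbance and orientation drift, asymmetric or twisted lifts, fatigue across
repetitions, and any force/torque content — so a passing suite demonstrates
the correctness of the computational chain and the detectability of
Table-level contrasts under idealized sensing, not field robustness.

## Features and datasets

One trial yields ten scalars: AP/ML/V excursion ranges of the displacement
vector (mm) and seven sagittal RoMs (deg), computed on the segmented,
time-normalized (101-point) window. Movement is bracketed by the mean hip
angular velocity exceeding 5% of its peak (smoothed at 3 Hz, sustained-run
hysteresis) — the event rule is this package's choice, as none is published;
explicit markers override it. The T-Ll set is all ten features; UpB keeps the
four trunk-related ones. Each repetition is one sample; sub-datasets are
keyed (task, load) with both postures pooled (156 rows for 26 subjects) and
*incorrect* as the positive class.

## Statistics

Per parameter and task, a 2 (posture) × 3 (load) fully within-subject ANOVA
on repetition means: standard SS decomposition with separate error strata,
Mauchly's test on the three-level factor and the interaction only (a
two-level factor satisfies sphericity trivially), Greenhouse–Geisser
correction applied when Mauchly p < 0.05, Bonferroni-adjusted paired
comparisons between loads, and — only when the interaction is significant —
posture breakdown by paired t-tests at each load, unadjusted. Missing cells
fail loudly; the design is balanced by protocol. `power_check` estimates the
posture-effect rejection rate by Monte-Carlo at the parameter level (drawing
subject condition means from the same distributions the trial simulator
uses), which keeps hundreds of replicates affordable; the full 40 Hz chain is
exercised separately on one complete cohort.

## Classification

`PostureSVM` is an sklearn-compatible estimator over four kernels: linear;
polynomial degree 2/3 with unit scale and offset; Gaussian with scale
1/n_features (natural after z-scoring); C = 1 throughout. These
hyperparameters are declared defaults, not tuned values. Leave-one-out
cross-validation predicts every row from all the others; z-scoring statistics
are computed per training fold by default (leakage-safe) with a `global`
mode reproducing a once-before-CV normalization; `group_by_subject` gives
leave-one-subject-out as a stricter alternative. Metrics are accuracy,
specificity, sensitivity and precision in percent, with zero-denominator
ratios reported as NaN; ROC curves pool the held-out decision scores, with
the Youden-optimal operating point marked. Wall times are recorded as
information only.

## Numerical choices and limitations

Rotation averaging uses the quaternion mean; orthonormality is preserved to
1e-9 through all compositions. The raised-cosine peak falls on the sample
grid at the default timing, so commanded RoMs are met to 1e-6° at zero noise;
at default noise the end-to-end joint-angle error is ≈1°. Problem sizes in
the shipped tests and the acceptance script (one 26-subject cohort, 200-
replicate power runs, 10 000-replicate null calibrations) were chosen as the
smallest sizes at which the Monte-Carlo bands quoted in the tests are
meaningful. Known limitations: sagittal-only joint angles, a single
anthropometric parameter (`l_trk`), no kinetics, and classifier accuracies
that depend on declared default hyperparameters.
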