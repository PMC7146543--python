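# liftkin

Wearable-IMU biomechanics of manual lifting: sensor-to-segment calibration,
sagittal joint kinematics, repeated-measures statistics, and squat-vs-stoop
posture classification.

Occupational lifting with a fully bent trunk and extended knees (*stoop*)
loads the spine far more than the recommended *squat* pattern (trunk near
upright, knees deeply flexed). `liftkin` is a pipeline for ergonomists and
movement scientists who instrument workers with eight body-worn orientation
sensors (sternum, pelvis, thighs, shanks, feet; unit-quaternion output at
40 Hz) and want to (i) quantify how posture and load change lifting
kinematics and (ii) detect unsafe lifts automatically.

## What it computes

**Kinematics.** After a functional calibration (5 s standing + 5 s sitting)
that estimates each constant segment←sensor rotation, the package computes
sagittal joint angles (lumbosacral, hips, knees, ankles; flexion /
dorsiflexion positive) from adjacent-segment relative rotations, and the
displacement of the trunk with respect to the pelvis. With the trunk origin
`o = [0, 0, l_trk]ᵀ` (trunk length in mm) and `R` the pelvis→trunk rotation,
the homogeneous transform `T = [R o; 0 1]` has inverse carrying `−Rᵀo`, and

    PT = o − (−Rᵀ o) = (I + Rᵀ) o

with antero-posterior (AP), medio-lateral (ML) and vertical (V) components in
the pelvis frame (mm).

**Features.** Per trial: the AP/ML/V excursion ranges of `PT` and the seven
joint ranges of motion, on the segmented, time-normalized movement cycle.
The full set (T-Ll, 10 features) uses all eight sensors; the trunk-only set
(UpB, 4 features) uses just the sternum and pelvis sensors.

**Statistics.** Per parameter and task, a 2 (posture) × 3 (load: 1/2/5 kg)
within-subject ANOVA on repetition means, with Mauchly's sphericity test,
Greenhouse–Geisser correction, Bonferroni post-hoc between loads, and paired
t-test breakdown of significant interactions.

**Classification.** An SVM (`PostureSVM`, sklearn-compatible) with linear,
quadratic, cubic and Gaussian kernels, evaluated by leave-one-out
cross-validation per (task, load) sub-dataset, reporting accuracy,
specificity (TNR), sensitivity (TPR), precision (PPV), confusion counts and
ROC curves; the positive class is the incorrect posture.

**Simulator.** Since no recordings of this protocol are public, a
forward-kinematic simulator generates the full study design (26 subjects × 2
tasks × 2 postures × 3 loads × 3 repetitions = 936 trials) with
condition-level joint excursions drawn from published squat/stoop contrast
distributions, plus mounting misalignment and orientation noise. Every stage
is validated against its ground truth; see `docs/methods.md`.

## Worked example

```python
from liftkin import config, pipeline

cfg = config.load_config({"seed": 1})     # default 26-subject cohort
res = pipeline.run_pipeline(cfg)

cond = res.condition_means
print(cond.groupby(["task", "posture"])[["rom_knee_r", "rom_sacr"]].mean().round(1))

a = res.anova["LL"]["rom_knee_r"]
print(f"LL knee RoM, posture effect: F{a.posture.df} = {a.posture.F:.1f}, p = {a.posture.p:.2g}")

rep = res.report
print(rep.groupby("feature_set")["acc"].agg(["min", "mean"]).round(1))
```

prints

```
                rom_knee_r  rom_sacr
task posture
LL   correct          97.2      37.8
     incorrect        20.5      53.7
RL   correct          98.6      42.1
     incorrect        21.1      55.8
LL knee RoM, posture effect: F(1, 25) = 705.9, p = 7.6e-20
               min   mean
feature_set
T-Ll         100.0  100.0
UpB           76.3   83.5
```

Squat trials flex the knee ~77° more and bend the trunk over the pelvis ~16°
less than stoop trials; the posture effect is overwhelming for every
parameter. With all ten kinematic features the leave-one-out SVM separates
the postures perfectly in every task × load × kernel cell, while the
trunk-only feature set stalls around 70–90% — lower-limb sensing is what
makes the classification reliable.

The same analysis is available from a shell:

```sh
liftkin all --seed 1 --out results/run1      # simulate → process → stats → classify
liftkin simulate --seed 1 --out recordings/  # write per-trial CSV+JSON bundles
```

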