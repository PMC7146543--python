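"""Forward-kinematic simulator of squat (correct) and stoop (incorrect)
lifting/releasing trials.

A planar seven-segment sagittal chain (feet–shanks–thighs–pelvis–trunk) is
driven by flexion-positive joint waveforms through one descent–ascent cycle
(raised-cosine half down, half up), with symmetric left/right motion plus a
small independent left/right jitter.  Segment orientations are composed with
per-segment nominal mounting rotations, a constant per-subject random mounting
misalignment, and small-angle white orientation noise (smoothed consistently
with the sensors' internal low-pass behaviour) to yield the eight 40 Hz
world←sensor quaternion streams a wearable IMU suite would record.

Condition-level joint excursions are drawn per subject from normal
distributions whose means and SDs are the cohort defaults in
:data:`CONDITION_TARGETS` (squat: trunk near upright, knees deeply flexed;
stoop: knees near extension, trunk fully bent; heavier loads increase hip
excursion and medio-lateral trunk sway).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .biomech import lowpass, trunk_pelvis_displacement
from .errors import ConfigurationError
from .frames import SEGMENTS, nominal_mounting, rot_ap, rot_ml
from .records import (
    GroundTruth,
    OrientationStream,
    StaticCapture,
    TrialMeta,
    TrialRecording,
)
from . import frames

TASKS = ("LL", "RL")
POSTURES = ("correct", "incorrect")

#: per-condition (task, posture) joint-excursion targets at the 1 kg load:
#: mean and between-subject SD, degrees.  ``trunk_pitch`` is the peak pitch of
#: the trunk *segment* (pelvis pitch is derived as trunk pitch minus the
#: lumbosacral excursion); ``ml_sway`` is the peak medio-lateral trunk lean.
CONDITION_TARGETS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("LL", "correct"): {
        "sacr": (36.7, 12.4),
        "hip": (99.4, 10.7),
        "knee": (102.1, 16.8),
        "ankle": (27.6, 7.9),
        "trunk_pitch": (50.0, 13.0),
        "ml_sway": (4.7, 2.2),
    },
    ("LL", "incorrect"): {
        "sacr": (52.5, 10.0),
        "hip": (75.3, 15.2),
        "knee": (29.6, 20.8),
        "ankle": (12.8, 4.9),
        "trunk_pitch": (95.0, 13.0),
        "ml_sway": (8.1, 2.8),
    },
    ("RL", "correct"): {
        "sacr": (39.3, 14.2),
        "hip": (100.4, 11.5),
        "knee": (104.1, 17.1),
        "ankle": (26.8, 7.7),
        "trunk_pitch": (52.0, 13.0),
        "ml_sway": (6.0, 2.3),
    },
    ("RL", "incorrect"): {
        "sacr": (55.0, 9.9),
        "hip": (75.0, 16.4),
        "knee": (28.2, 19.3),
        "ankle": (12.4, 4.1),
        "trunk_pitch": (97.0, 13.0),
        "ml_sway": (9.4, 3.0),
    },
}

#: correlation of a subject's parameter value across the four conditions (a
#: "trait" component): lifters who sway or flex more do so in every condition.
#: Trunk sway is an individual style almost invariant across conditions, which
#: is what makes its small posture contrast detectable in a paired design.
PARAM_CORRELATION = {
    "sacr": 0.8,
    "hip": 0.8,
    "knee": 0.8,
    "ankle": 0.8,
    "trunk_pitch": 0.8,
    "ml_sway": 0.97,
}


@dataclass
class MotionProfile:
    """Joint targets and timing of one simulated descent–ascent cycle."""

    sacr_deg: float
    hip_deg: float
    knee_deg: float
    ankle_deg: float
    trunk_pitch_deg: float
    ml_sway_deg: float = 0.0
    duration_s: float = 4.0
    descent_frac: float = 0.5
    lead_s: float = 0.5
    tail_s: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sacr_deg", "hip_deg", "knee_deg", "ankle_deg"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.duration_s <= 0:
            raise ConfigurationError("duration must be positive")
        if not 0.0 < self.descent_frac < 1.0:
            raise ConfigurationError("descent fraction must lie in (0, 1)")


@dataclass
class CohortSpec:
    """Study-design and noise parameters of a simulated cohort."""

    n_subjects: int = 26
    tasks: tuple[str, ...] = TASKS
    postures: tuple[str, ...] = POSTURES
    loads_kg: tuple[float, ...] = (1.0, 2.0, 5.0)
    repetitions: int = 3
    fs_hz: float = 40.0
    hip_load_slope_deg_per_kg: float = 1.2
    ml_load_slope_deg_per_kg: float = 0.2
    variability_scale: float = 1.0  # multiplies all between-subject SDs
    rep_jitter_deg: float = 3.0  # within-subject repetition SD
    ml_rep_jitter_deg: float = 0.8  # repetition SD of the ML sway amplitude
    lr_jitter_deg: float = 1.5  # independent left/right amplitude SD
    orientation_noise_deg: float = 0.3
    misalignment_deg: float = 3.0
    seed: int = 0
    targets: dict = field(default_factory=lambda: CONDITION_TARGETS)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")
        for name in ("orientation_noise_deg", "misalignment_deg", "rep_jitter_deg", "lr_jitter_deg"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        bad = [t for t in self.tasks if t not in TASKS]
        bad += [p for p in self.postures if p not in POSTURES]
        if bad:
            raise ConfigurationError(f"unknown task/posture labels: {bad}")

    @classmethod
    def noise_free(cls, **kw) -> "CohortSpec":
        """All random components switched off: draws equal condition means."""
        kw.setdefault("variability_scale", 0.0)
        kw.setdefault("rep_jitter_deg", 0.0)
        kw.setdefault("ml_rep_jitter_deg", 0.0)
        kw.setdefault("lr_jitter_deg", 0.0)
        kw.setdefault("orientation_noise_deg", 0.0)
        kw.setdefault("misalignment_deg", 0.0)
        return cls(**kw)


@dataclass
class SubjectParams:
    """Per-subject anthropometrics, condition baselines and sensor placement."""

    subject_id: str
    l_trk_mm: float
    baselines: dict  # (task, posture) -> {param: deg at the 1 kg load}
    misalignment: dict  # segment -> Rotation (sensor-frame mounting error)
    spec: CohortSpec


def draw_subject(spec: CohortSpec, rng: np.random.Generator, index: int = 0) -> SubjectParams:
    """Sample one subject's condition baselines, trunk length and mounting.

    Joint excursions are drawn N(mean, scale·SD) per condition and truncated
    at zero; the trunk length is drawn in a plausible adult band (400–600 mm).
    """
    scale = spec.variability_scale
    l_trk = float(np.clip(rng.normal(500.0, 40.0 * scale), 400.0, 600.0))
    param_names = sorted({n for params in spec.targets.values() for n in params})
    traits = {name: rng.standard_normal() for name in param_names}
    baselines = {}
    for key, params in spec.targets.items():
        cond = {}
        for name, (mean, sd) in params.items():
            rho = PARAM_CORRELATION.get(name, 0.8)
            z = rho * traits[name] + np.sqrt(1.0 - rho**2) * rng.standard_normal()
            cond[name] = max(0.0, mean + sd * scale * float(z))
        baselines[key] = cond
    misalign = {}
    sd_rad = np.deg2rad(spec.misalignment_deg)
    for seg in SEGMENTS:
        rv = rng.normal(0.0, sd_rad, size=3) if sd_rad > 0 else np.zeros(3)
        misalign[seg] = Rotation.from_rotvec(rv)
    return SubjectParams(
        subject_id=f"S{index:02d}",
        l_trk_mm=l_trk,
        baselines=baselines,
        misalignment=misalign,
        spec=spec,
    )


def raised_cosine(u: np.ndarray, descent_frac: float) -> np.ndarray:
    """Smooth unimodal 0→1→0 waveform on u ∈ [0, 1], peak at ``descent_frac``."""
    w = np.zeros_like(u)
    d = descent_frac
    down = (u >= 0) & (u <= d)
    up = (u > d) & (u <= 1)
    w[down] = 0.5 * (1.0 - np.cos(np.pi * u[down] / d))
    w[up] = 0.5 * (1.0 + np.cos(np.pi * (u[up] - d) / (1.0 - d)))
    return w


def _mounted(r_w_seg: Rotation, seg: str, subject: SubjectParams, mounting: dict[str, Rotation]) -> Rotation:
    return r_w_seg * (mounting[seg] * subject.misalignment[seg])


def _noisy(r: Rotation, noise_deg: float, fs: float, rng: np.random.Generator) -> Rotation:
    if noise_deg <= 0:
        return r
    n = len(r)
    rv = rng.normal(0.0, np.deg2rad(noise_deg), size=(n, 3))
    if n > 8:  # smooth like the sensors' internal filtering
        rv = lowpass(rv, fs, fc=10.0, order=2)
    return r * Rotation.from_rotvec(rv)


def motion_profile(subject: SubjectParams, task: str, posture: str, load_kg: float) -> MotionProfile:
    """The subject's noise-free joint targets for one condition."""
    spec = subject.spec
    base = subject.baselines[(task, posture)]
    return MotionProfile(
        sacr_deg=base["sacr"],
        hip_deg=base["hip"] + spec.hip_load_slope_deg_per_kg * (load_kg - 1.0),
        knee_deg=base["knee"],
        ankle_deg=base["ankle"],
        trunk_pitch_deg=base["trunk_pitch"],
        # stooping lifters sway more as the load grows; squatters hardly change
        ml_sway_deg=base["ml_sway"]
        + spec.ml_load_slope_deg_per_kg
        * (1.0 if posture == "incorrect" else 0.3)
        * (load_kg - 1.0),
        descent_frac=0.55 if posture == "incorrect" else 0.5,  # faster ascent when stooping
    )


def simulate_trial(
    subject: SubjectParams,
    task: str,
    posture: str,
    load_kg: float,
    repetition: int,
    rng: np.random.Generator,
) -> tuple[TrialRecording, GroundTruth]:
    """Simulate one trial: 8 sensor streams plus the ground-truth kinematics."""
    if task not in TASKS or posture not in POSTURES:
        raise ConfigurationError(f"unknown task/posture: {task!r}/{posture!r}")
    spec = subject.spec
    prof = motion_profile(subject, task, posture, load_kg)
    fs = spec.fs_hz
    n = int(round((prof.lead_s + prof.duration_s + prof.tail_s) * fs)) + 1
    t = np.arange(n) / fs
    u = (t - prof.lead_s) / prof.duration_s
    w = raised_cosine(u, prof.descent_frac)

    def amp(x: float) -> dict[str, float]:
        jit = rng.normal(0.0, spec.rep_jitter_deg) if spec.rep_jitter_deg > 0 else 0.0
        lr = (
            rng.normal(0.0, spec.lr_jitter_deg, size=2)
            if spec.lr_jitter_deg > 0
            else np.zeros(2)
        )
        return {"l": max(0.0, x + jit + lr[0]), "r": max(0.0, x + jit + lr[1])}

    sacr = max(0.0, prof.sacr_deg + (rng.normal(0.0, spec.rep_jitter_deg) if spec.rep_jitter_deg > 0 else 0.0))
    hip = amp(prof.hip_deg)
    knee = amp(prof.knee_deg)
    ankle = amp(prof.ankle_deg)
    ml = max(
        0.0,
        prof.ml_sway_deg
        + (rng.normal(0.0, spec.ml_rep_jitter_deg) if spec.ml_rep_jitter_deg > 0 else 0.0),
    )

    pelvis_amp = max(0.0, prof.trunk_pitch_deg - sacr)
    phi = {"pelvis": pelvis_amp * w}
    joints = {"sacr": sacr * w}
    phi["trunk"] = phi["pelvis"] + joints["sacr"]
    for side in ("l", "r"):
        joints[f"hip_{side}"] = hip[side] * w
        joints[f"knee_{side}"] = knee[side] * w
        joints[f"ankle_{side}"] = ankle[side] * w
        phi[f"thigh_{side}"] = phi["pelvis"] + joints[f"hip_{side}"]
        phi[f"shank_{side}"] = phi[f"thigh_{side}"] - joints[f"knee_{side}"]
        phi[f"foot_{side}"] = phi[f"shank_{side}"] - joints[f"ankle_{side}"]
    roll = ml * w

    seg_rot = {seg: rot_ml(phi[seg]) for seg in SEGMENTS if seg != "trunk"}
    seg_rot["trunk"] = rot_ml(phi["trunk"]) * rot_ap(roll)

    mounting = nominal_mounting()
    streams = {}
    for seg in SEGMENTS:
        r_sen = _noisy(_mounted(seg_rot[seg], seg, subject, mounting), spec.orientation_noise_deg, fs, rng)
        streams[seg] = OrientationStream.from_rotations(seg, t, r_sen, fs)

    r_pl_trk = rot_ml(joints["sacr"]) * rot_ap(roll)
    pt = trunk_pelvis_displacement(r_pl_trk, subject.l_trk_mm)
    events = {
        "start_s": prof.lead_s,
        "end_s": prof.lead_s + prof.duration_s,
        "peak_s": prof.lead_s + prof.descent_frac * prof.duration_s,
    }
    meta = TrialMeta(
        subject_id=subject.subject_id,
        task=task,
        posture=posture,
        load_kg=float(load_kg),
        repetition=int(repetition),
        l_trk_mm=subject.l_trk_mm,
        fs_hz=fs,
        events=dict(events),
        mounting_wxyz={
            seg: frames.quat_wxyz_from_rotation(mounting[seg])[0].tolist() for seg in SEGMENTS
        },
    )
    truth = GroundTruth(t=t, joints_deg=joints, pt_mm=pt, events=events)
    return TrialRecording(meta=meta, streams=streams), truth


#: static sitting pose: pelvis posteriorly tilted, hips and knees flexed so the
#: thighs are horizontal (pitch ≈ 90°) and the shanks vertical (pitch ≈ 0°)
_SITTING_POSE = {"pelvis": 20.0, "sacr": 10.0, "hip": 70.0, "knee": 90.0, "ankle": 0.0}


def simulate_calibration(
    subject: SubjectParams, rng: np.random.Generator, duration_s: float = 5.0
) -> tuple[StaticCapture, StaticCapture]:
    """Standing and sitting static captures for the functional calibration."""
    spec = subject.spec
    fs = spec.fs_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    mounting = nominal_mounting()

    def capture(pose_name: str, phi: dict[str, float]) -> StaticCapture:
        streams = {}
        for seg in SEGMENTS:
            base = rot_ml(np.full(n, phi.get(seg, 0.0)))
            r_sen = _noisy(_mounted(base, seg, subject, mounting), spec.orientation_noise_deg, fs, rng)
            streams[seg] = OrientationStream.from_rotations(seg, t, r_sen, fs)
        return StaticCapture(pose=pose_name, streams=streams)

    standing = capture("standing", {})
    p = _SITTING_POSE
    phi_sit = {
        "pelvis": p["pelvis"],
        "trunk": p["pelvis"] + p["sacr"],
    }
    for side in ("l", "r"):
        phi_sit[f"thigh_{side}"] = p["pelvis"] + p["hip"]
        phi_sit[f"shank_{side}"] = phi_sit[f"thigh_{side}"] - p["knee"]
        phi_sit[f"foot_{side}"] = phi_sit[f"shank_{side}"] - p["ankle"]
    sitting = capture("sitting", phi_sit)
    return standing, sitting


@dataclass
class SimulatedTrial:
    recording: TrialRecording
    truth: GroundTruth


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    subjects: list[SubjectParams]
    calibrations: dict[str, tuple[StaticCapture, StaticCapture]]
    trials: list[SimulatedTrial]


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Simulate the full protocol: subjects × tasks × postures × loads × reps.

    Deterministic under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = [draw_subject(spec, rng, index=i + 1) for i in range(spec.n_subjects)]
    calibrations = {}
    trials: list[SimulatedTrial] = []
    for subject in subjects:
        calibrations[subject.subject_id] = simulate_calibration(subject, rng)
        for task in spec.tasks:
            for posture in spec.postures:
                for load in spec.loads_kg:
                    for rep in range(1, spec.repetitions + 1):
                        rec, truth = simulate_trial(subject, task, posture, load, rep, rng)
                        trials.append(SimulatedTrial(recording=rec, truth=truth))
    return SimulatedCohort(spec=spec, subjects=subjects, calibrations=calibrations, trials=trials)
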