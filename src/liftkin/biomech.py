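"""Biomechanical model: preprocessing, functional calibration, segment poses,
sagittal joint angles and the pelvis–trunk displacement vector.

The model instruments seven segments (trunk, pelvis, thighs, shanks, feet) with
one orientation sensor each.  A functional calibration built from a standing
and a sitting static capture yields the constant segment←sensor rotation; trial
orientations are then mapped to segment poses, adjacent-segment relative
rotations give the sagittal joint angles, and the pelvis–trunk relative
rotation together with the anthropometric trunk length ``l_trk`` gives the
trunk displacement vector expressed in the pelvis frame:

    o = [0, 0, l_trk]^T                 (trunk origin in the pelvis frame)
    PT = o - (-R^T o) = (I + R^T) o     (R = pelvis→trunk relative rotation)

with components reported as AP = y, ML = x, V = z of the pelvis frame, in mm.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .errors import CalibrationError, ConfigurationError, InputError
from .frames import JOINT_SIGN, JOINT_TOPOLOGY, SEGMENTS, rotation_angle_deg
from .records import (
    SegmentFrameMap,
    SegmentPose,
    StaticCapture,
    TrialRecording,
    kinematics_frame,
)

_Z = np.array([0.0, 0.0, 1.0])
_Y = np.array([0.0, 1.0, 0.0])

#: segments whose medio-lateral axis is identified from the standing→sitting
#: relative-rotation axis (they rotate substantially about it when sitting
#: down); the rest inherit the anterior axis from the standing heading.
_AXIS_SEGMENTS = ("pelvis", "thigh_l", "thigh_r")


# ---------------------------------------------------------------------------
# filtering


def lowpass(
    x: np.ndarray,
    fs: float,
    fc: float = 10.0,
    order: int = 2,
    method: str = "fft",
) -> np.ndarray:
    """Zero-phase low-pass filter with a Butterworth magnitude response.

    The default implementation multiplies the (reflect-padded) spectrum by the
    analog Butterworth magnitude ``1/sqrt(1 + (f/fc)^(2·order))``, which is
    zero-phase by construction and matches the analog response at every
    frequency (a recursive bilinear design warps noticeably once the signal
    content approaches the Nyquist rate).  ``method="filtfilt"`` selects the
    conventional forward–backward recursive route instead.

    Applied column-wise to 2-D input.  Never apply this to raw quaternion
    components; filter a rotation-vector or angle representation instead.
    """
    if fs <= 2.0 * fc:
        raise ConfigurationError(f"sampling rate {fs} Hz must exceed twice the cutoff {fc} Hz")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return lowpass(x[:, None], fs, fc, order, method)[:, 0]
    n = x.shape[0]
    if n < 3:
        return x.copy()
    if method == "filtfilt":
        sos = signal.butter(order, fc, fs=fs, output="sos")
        return signal.sosfiltfilt(sos, x, axis=0)
    if method != "fft":
        raise ConfigurationError(f"unknown filter method {method!r}")
    pad = min(n - 1, max(8, int(round(fs))))  # ~1 s reflect padding
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -2 - pad : -1]], axis=0)
    freqs = np.fft.rfftfreq(xp.shape[0], d=1.0 / fs)
    gain = 1.0 / np.sqrt(1.0 + (freqs / fc) ** (2 * order))
    spec = np.fft.rfft(xp, axis=0)
    out = np.fft.irfft(spec * gain[:, None], n=xp.shape[0], axis=0)
    return out[pad : pad + n]


def filter_rotations(r: Rotation, fs: float, fc: float = 10.0, order: int = 2, method: str = "fft") -> Rotation:
    """Low-pass a rotation series through its rotation-vector representation.

    The series is referenced to its first sample before conversion, so the
    filtered rotation vectors stay far from the ±180° branch cut of the
    axis–angle map regardless of how the sensor is mounted (the excursion from
    the initial pose, not the absolute orientation, must stay below 180°).
    """
    anchor = r[0]
    rv = (anchor.inv() * r).as_rotvec()
    return anchor * Rotation.from_rotvec(lowpass(rv, fs, fc, order, method))


def preprocess_recording(
    recording: TrialRecording, fc: float = 10.0, order: int = 2, method: str = "fft"
) -> TrialRecording:
    """Return a copy of the recording with every stream low-pass filtered."""
    from .records import OrientationStream  # local to avoid cycle in type hints

    fs = recording.meta.fs_hz
    streams = {}
    for seg, s in recording.streams.items():
        filtered = filter_rotations(s.rotations(), fs, fc, order, method)
        streams[seg] = OrientationStream.from_rotations(s.sensor_id, s.t, filtered, fs)
    return TrialRecording(meta=recording.meta, streams=streams)


# ---------------------------------------------------------------------------
# functional calibration


def _static_mean(capture: StaticCapture, seg: str, motion_tol_deg: float) -> Rotation:
    r = capture.streams[seg].rotations()
    mean = r.mean()
    dev = rotation_angle_deg(mean.inv() * r)
    if np.max(dev) > motion_tol_deg:
        raise CalibrationError(
            f"{capture.pose} capture: {seg} moved {np.max(dev):.1f} deg (tolerance {motion_tol_deg} deg)"
        )
    return mean


def functional_calibration(
    standing: StaticCapture,
    sitting: StaticCapture,
    nominal: dict[str, Rotation] | None = None,
    motion_tol_deg: float = 3.0,
    min_sit_angle_deg: float = 5.0,
    mismatch_warn_deg: float = 20.0,
) -> SegmentFrameMap:
    """Estimate the constant segment←sensor rotation from two static captures.

    The standing capture fixes each segment's vertical axis (gravity, world z,
    expressed in the sensor frame).  For the pelvis and thighs the
    standing→sitting relative rotation happens about the medio-lateral axis
    (hip flexion / pelvic tilt), so its rotation axis, projected orthogonal to
    the vertical, fixes x; the remaining segments barely rotate when sitting
    down and inherit their anterior axis from the standing heading.

    If ``nominal`` mounting rotations are given, a recovered map deviating by
    more than ``mismatch_warn_deg`` raises a warning flag (e.g. a tilted
    "standing" capture violating the upright assumption).
    """
    missing = [s for s in SEGMENTS if s not in standing.streams or s not in sitting.streams]
    if missing:
        raise InputError(f"calibration captures missing segments: {', '.join(missing)}")
    maps: dict[str, Rotation] = {}
    quality: dict[str, float] = {}
    flagged: list[str] = []
    for seg in SEGMENTS:
        r_stand = _static_mean(standing, seg, motion_tol_deg)
        z_s = r_stand.inv().apply(_Z)
        if seg in _AXIS_SEGMENTS:
            r_sit = _static_mean(sitting, seg, motion_tol_deg)
            rel = r_stand.inv() * r_sit
            rotvec = rel.as_rotvec()
            angle = np.linalg.norm(rotvec)
            if np.rad2deg(angle) < min_sit_angle_deg:
                raise CalibrationError(
                    f"{seg}: standing→sitting rotation only {np.rad2deg(angle):.1f} deg; "
                    "cannot identify the medio-lateral axis"
                )
            x_s = rotvec / angle
            x_s = x_s - np.dot(x_s, z_s) * z_s
            x_s /= np.linalg.norm(x_s)
            y_s = np.cross(z_s, x_s)
        else:
            y0 = r_stand.inv().apply(_Y)
            y_s = y0 - np.dot(y0, z_s) * z_s
            y_s /= np.linalg.norm(y_s)
            x_s = np.cross(y_s, z_s)
        m = np.vstack([x_s, y_s, z_s])  # rows: segment axes in sensor coords
        maps[seg] = Rotation.from_matrix(m)
        if nominal is not None and seg in nominal:
            mismatch = float(rotation_angle_deg(maps[seg] * nominal[seg].inv())[0])
            quality[seg] = mismatch
            if mismatch > mismatch_warn_deg:
                flagged.append(seg)
    warns = []
    if flagged:
        msg = (
            "functional calibration deviates strongly from the nominal mounting for "
            f"{', '.join(flagged)}; check the standing capture"
        )
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
    return SegmentFrameMap(maps=maps, quality=quality, warnings=warns)


# ---------------------------------------------------------------------------
# poses, joint angles, displacement


def segment_poses(recording: TrialRecording, fmap: SegmentFrameMap) -> SegmentPose:
    """World←segment rotation series: (world←sensor) ∘ (segment←sensor)⁻¹."""
    missing = [s for s in SEGMENTS if s not in fmap.maps]
    if missing:
        raise InputError(f"frame map missing segments: {', '.join(missing)}")
    rotations = {
        seg: recording.streams[seg].rotations() * fmap.maps[seg].inv() for seg in SEGMENTS
    }
    return SegmentPose(t=recording.t, rotations=rotations)


def sagittal_angle_deg(r_rel: Rotation) -> np.ndarray:
    """First angle of the medio-lateral-axis-first Euler decomposition, deg."""
    return np.rad2deg(np.atleast_2d(r_rel.as_euler("XYZ"))[:, 0])


def joint_angles(poses: SegmentPose) -> dict[str, np.ndarray]:
    """Sagittal joint angles (deg), flexion/dorsiflexion positive.

    Each joint angle is extracted from the relative rotation between its two
    adjacent segment frames, ``R_rel = R_parentᵀ · R_child``; a common world
    rotation applied to all poses cancels exactly.
    """
    out: dict[str, np.ndarray] = {}
    for joint, (parent, child) in JOINT_TOPOLOGY.items():
        if parent not in poses.rotations or child not in poses.rotations:
            raise InputError(f"poses missing {parent} or {child} for joint {joint}")
        r_rel = poses.rotations[parent].inv() * poses.rotations[child]
        out[joint] = JOINT_SIGN[joint] * sagittal_angle_deg(r_rel)
    return out


def pelvis_trunk_rotation(poses: SegmentPose) -> Rotation:
    """Pelvis→trunk relative rotation series (^pl R_trk)."""
    return poses.rotations["pelvis"].inv() * poses.rotations["trunk"]


def trunk_pelvis_displacement(r_pl_trk: Rotation, l_trk_mm: float) -> np.ndarray:
    """Displacement of the trunk segment w.r.t. the pelvis, in mm.

    Implements the homogeneous-transform construction literally: with the trunk
    origin ``o = [0, 0, l_trk]`` in the pelvis frame and ``R`` the pelvis→trunk
    rotation, the inverse roto-translation carries ``-Rᵀ·o`` and the
    displacement is ``PT = o - (-Rᵀ·o) = (I + Rᵀ)·o``, degree-1 homogeneous in
    ``l_trk``.  Returns an (n, 3) array with columns AP (y), ML (x), V (z).
    """
    if l_trk_mm <= 0:
        raise ConfigurationError(f"trunk length must be positive, got {l_trk_mm}")
    o = np.array([0.0, 0.0, float(l_trk_mm)])
    rt = r_pl_trk.inv()  # Rᵀ as a rotation
    o_trk_pl = -rt.apply(o)  # ^trk o_trk,pl
    pt = o - o_trk_pl
    pt = np.atleast_2d(pt)
    return np.column_stack([pt[:, 1], pt[:, 0], pt[:, 2]])


def process_trial(
    recording: TrialRecording,
    fmap: SegmentFrameMap,
    fc: float = 10.0,
    order: int = 2,
    filter_method: str = "fft",
):
    """Full per-trial kinematics: filter → poses → joint angles → displacement.

    Returns the canonical kinematics table (time, seven joint angles in deg,
    three displacement components in mm).
    """
    filtered = preprocess_recording(recording, fc=fc, order=order, method=filter_method)
    poses = segment_poses(filtered, fmap)
    joints = joint_angles(poses)
    pt = trunk_pelvis_displacement(pelvis_trunk_rotation(poses), recording.meta.l_trk_mm)
    return kinematics_frame(poses.t, joints, pt)
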