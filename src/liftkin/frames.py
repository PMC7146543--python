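"""Coordinate conventions shared by the simulator and the biomechanical model.

World frame: ``x`` medio-lateral, ``y`` antero-posterior (anterior positive),
``z`` vertical pointing up; the sagittal plane is the y–z plane.  Every body
segment carries a frame that coincides with the world frame in the neutral
standing pose.

Sagittal joint angles are rotations about the medio-lateral ``x`` axis.  The
sign convention is fixed once: *flexion* (lumbosacral, hip, knee) and *ankle
dorsiflexion* are positive, with the sign chosen so that positive lumbosacral
flexion produces a positive antero-posterior component of the pelvis–trunk
displacement vector.  Concretely, a joint at angle ``θ`` contributes
``R_x(SIGN[joint]·θ)`` to the child segment's orientation.

Quaternions are Hamilton, scalar-first ``(w, x, y, z)``, and always encode
world←sensor (the orientation a commercial IMU reports).  All internal math
uses rotation matrices via :class:`scipy.spatial.transform.Rotation`.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

#: the eight sensor placements / the segments they instrument
SEGMENTS = (
    "trunk",
    "pelvis",
    "thigh_l",
    "thigh_r",
    "shank_l",
    "shank_r",
    "foot_l",
    "foot_r",
)

#: sensor placement names as worn on the body (one IMU per segment)
PLACEMENTS = {
    "trunk": "sternum",
    "pelvis": "pelvis",
    "thigh_l": "thigh_l",
    "thigh_r": "thigh_r",
    "shank_l": "shank_l",
    "shank_r": "shank_r",
    "foot_l": "foot_l",
    "foot_r": "foot_r",
}

#: joint -> (parent segment, child segment stem); sides expand to _l/_r
JOINT_TOPOLOGY = {
    "sacr": ("pelvis", "trunk"),
    "hip_l": ("pelvis", "thigh_l"),
    "hip_r": ("pelvis", "thigh_r"),
    "knee_l": ("thigh_l", "shank_l"),
    "knee_r": ("thigh_r", "shank_r"),
    "ankle_l": ("shank_l", "foot_l"),
    "ankle_r": ("shank_r", "foot_r"),
}

#: sign mapping anatomical (flexion/dorsiflexion positive) angle -> rotation
#: about +x of the parent frame.  Chosen so the chain reproduces physically
#: sensible poses (sitting: thigh pitch +90 deg, shank pitch 0) while keeping
#: lumbosacral flexion positive about +x (required by the displacement-vector
#: sign convention).
JOINT_SIGN = {
    "sacr": +1.0,
    "hip_l": +1.0,
    "hip_r": +1.0,
    "knee_l": -1.0,
    "knee_r": -1.0,
    "ankle_l": -1.0,
    "ankle_r": -1.0,
}

JOINTS = tuple(JOINT_TOPOLOGY)


def rot_ml(angle_deg: np.ndarray | float) -> Rotation:
    """Rotation about the medio-lateral (x) axis, degrees, vectorized."""
    angle = np.atleast_1d(np.asarray(angle_deg, dtype=float))
    rv = np.zeros((angle.size, 3))
    rv[:, 0] = np.deg2rad(angle)
    r = Rotation.from_rotvec(rv)
    return r


def rot_ap(angle_deg: np.ndarray | float) -> Rotation:
    """Rotation about the antero-posterior (y) axis, degrees (trunk sway)."""
    angle = np.atleast_1d(np.asarray(angle_deg, dtype=float))
    rv = np.zeros((angle.size, 3))
    rv[:, 1] = np.deg2rad(angle)
    return Rotation.from_rotvec(rv)


def quat_wxyz_from_rotation(r: Rotation) -> np.ndarray:
    """Scalar-first unit quaternions with a canonical (w >= 0) sign."""
    q = r.as_quat()  # scipy: (x, y, z, w)
    q = np.atleast_2d(q)
    wxyz = np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])
    flip = wxyz[:, 0] < 0
    wxyz[flip] *= -1.0
    return wxyz


def rotation_from_quat_wxyz(q: np.ndarray) -> Rotation:
    """Rotation from scalar-first quaternions (renormalizes)."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    xyzw = np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]])
    return Rotation.from_quat(xyzw)  # scipy normalizes


def rotation_angle_deg(r: Rotation) -> np.ndarray:
    """Geodesic rotation angle(s) in degrees."""
    return np.rad2deg(np.atleast_1d(r.magnitude()))


#: nominal mounting rotations, segment←sensor, one per segment.  These emulate
#: how an IMU case sits on the body (e.g. flat on the sternum, lateral on the
#: thighs); the functional calibration must recover them (composed with any
#: subject-specific misalignment) from the static captures alone.
_NOMINAL_EULER_DEG = {
    "trunk": ("z", 180.0),
    "pelvis": ("x", 90.0),
    "thigh_l": ("y", 90.0),
    "thigh_r": ("y", -90.0),
    "shank_l": ("x", -90.0),
    "shank_r": ("z", 90.0),
    "foot_l": ("z", 0.0),
    "foot_r": ("x", 180.0),
}


def nominal_mounting() -> dict[str, Rotation]:
    """Default segment←sensor mounting rotation per segment."""
    return {
        seg: Rotation.from_euler(axis, ang, degrees=True)
        for seg, (axis, ang) in _NOMINAL_EULER_DEG.items()
    }
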