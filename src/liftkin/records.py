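"""In-memory containers for recordings, calibration maps and kinematics."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import InputError, NumericError
from .frames import SEGMENTS, quat_wxyz_from_rotation, rotation_from_quat_wxyz

#: canonical column order of a kinematics table
KINEMATIC_COLUMNS = (
    "time_s",
    "sacr_deg",
    "hip_l_deg",
    "hip_r_deg",
    "knee_l_deg",
    "knee_r_deg",
    "ankle_l_deg",
    "ankle_r_deg",
    "pt_ap_mm",
    "pt_ml_mm",
    "pt_v_mm",
)


@dataclass
class OrientationStream:
    """One sensor's world←sensor unit-quaternion series at a fixed rate.

    ``q`` is scalar-first (w, x, y, z), one row per sample; ``t`` is seconds,
    uniform at ``fs_hz``.
    """

    sensor_id: str
    t: np.ndarray
    q: np.ndarray
    fs_hz: float = 40.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] != 4:
            raise InputError(f"{self.sensor_id}: quaternion array must be (n, 4)")
        if self.t.shape[0] != self.q.shape[0]:
            raise InputError(f"{self.sensor_id}: t and q lengths differ")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise InputError(f"{self.sensor_id}: time must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.fs_hz, atol=1e-6):
                raise InputError(f"{self.sensor_id}: non-uniform sampling (expect fs={self.fs_hz})")

    def __len__(self) -> int:
        return self.t.shape[0]

    def rotations(self) -> Rotation:
        return rotation_from_quat_wxyz(self.q)

    @classmethod
    def from_rotations(cls, sensor_id: str, t: np.ndarray, r: Rotation, fs_hz: float = 40.0) -> "OrientationStream":
        return cls(sensor_id=sensor_id, t=np.asarray(t, float), q=quat_wxyz_from_rotation(r), fs_hz=fs_hz)


@dataclass
class TrialMeta:
    """Trial metadata and anthropometrics."""

    subject_id: str
    task: str  # "LL" | "RL"
    posture: str  # "correct" | "incorrect"
    load_kg: float
    repetition: int
    l_trk_mm: float
    fs_hz: float = 40.0
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    events: Optional[dict] = None  # optional {"start_s": float, "end_s": float}
    mounting_wxyz: Optional[dict] = None  # segment -> nominal mounting quat


@dataclass
class TrialRecording:
    """Eight named orientation streams plus metadata."""

    meta: TrialMeta
    streams: dict[str, OrientationStream]

    def __post_init__(self) -> None:
        missing = [s for s in SEGMENTS if s not in self.streams]
        if missing:
            raise InputError(f"missing sensor streams: {', '.join(missing)}")
        lengths = {len(s) for s in self.streams.values()}
        if len(lengths) != 1:
            raise InputError(f"sensor streams have unequal lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.streams.values())))

    @property
    def t(self) -> np.ndarray:
        return next(iter(self.streams.values())).t


@dataclass
class StaticCapture:
    """A short near-static capture (standing or sitting) of all 8 sensors."""

    pose: str  # "standing" | "sitting"
    streams: dict[str, OrientationStream]


@dataclass
class SegmentFrameMap:
    """Constant segment←sensor rotation per segment from functional calibration.

    ``maps[seg]`` satisfies ``v_segment = maps[seg].apply(v_sensor)``.
    """

    maps: dict[str, Rotation]
    quality: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for seg, r in self.maps.items():
            m = r.as_matrix()
            if m.ndim != 2 or not np.allclose(m @ m.T, np.eye(3), atol=1e-8):
                raise NumericError(f"{seg}: sensor-to-segment rotation not orthonormal")


@dataclass
class SegmentPose:
    """World←segment rotation series per segment, one common clock."""

    t: np.ndarray
    rotations: dict[str, Rotation]

    def __post_init__(self) -> None:
        n = self.t.shape[0]
        for seg, r in self.rotations.items():
            if len(r) != n:
                raise InputError(f"{seg}: pose length {len(r)} != {n}")


@dataclass
class GroundTruth:
    """Simulator truth sampled on the trial clock."""

    t: np.ndarray
    joints_deg: dict[str, np.ndarray]  # per JOINTS key
    pt_mm: np.ndarray  # (n, 3) columns AP, ML, V
    events: dict  # {"start_s", "end_s", "peak_s"}

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.t})
        for j, v in self.joints_deg.items():
            df[f"{j}_deg"] = v
        df["pt_ap_mm"] = self.pt_mm[:, 0]
        df["pt_ml_mm"] = self.pt_mm[:, 1]
        df["pt_v_mm"] = self.pt_mm[:, 2]
        return df


def kinematics_frame(t: np.ndarray, joints_deg: dict[str, np.ndarray], pt_mm: np.ndarray) -> pd.DataFrame:
    """Assemble the canonical kinematics table."""
    df = pd.DataFrame({"time_s": t})
    for j in ("sacr", "hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r"):
        df[f"{j}_deg"] = joints_deg[j]
    df["pt_ap_mm"] = pt_mm[:, 0]
    df["pt_ml_mm"] = pt_mm[:, 1]
    df["pt_v_mm"] = pt_mm[:, 2]
    return df[list(KINEMATIC_COLUMNS)]


__all__ = [
    "OrientationStream",
    "TrialMeta",
    "TrialRecording",
    "StaticCapture",
    "SegmentFrameMap",
    "SegmentPose",
    "GroundTruth",
    "KINEMATIC_COLUMNS",
    "kinematics_frame",
    "replace",
]
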