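"""Recording bundle format: one directory per trial holding ``metadata.json``
plus one CSV per sensor placement (``time_s,qw,qx,qy,qz``, UTF-8, mandatory
header, '.' decimal).  Values round-trip bit-stably through their textual
representation (repr-precision floats).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .frames import SEGMENTS
from .records import GroundTruth, OrientationStream, TrialMeta, TrialRecording

SENSOR_HEADER = ("time_s", "qw", "qx", "qy", "qz")
_QNORM_TOL = 1e-3


def write_recording(recording: TrialRecording, path: str | Path) -> Path:
    """Write a trial bundle (metadata JSON + 8 per-sensor CSVs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dataclasses.asdict(recording.meta)
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    for seg, stream in recording.streams.items():
        df = pd.DataFrame(
            np.column_stack([stream.t, stream.q]), columns=list(SENSOR_HEADER)
        )
        df.to_csv(path / f"{seg}.csv", index=False, float_format="%.17g")
    return path


def read_recording(path: str | Path) -> TrialRecording:
    """Read a trial bundle, validating structure and quaternion norms."""
    path = Path(path)
    meta_file = path / "metadata.json"
    if not meta_file.exists():
        raise FormatError(f"{path}: missing metadata.json")
    try:
        meta_raw = json.loads(meta_file.read_text())
        meta = TrialMeta(**meta_raw)
    except (json.JSONDecodeError, TypeError) as exc:
        raise FormatError(f"{meta_file}: invalid metadata ({exc})") from exc
    missing = [seg for seg in SEGMENTS if not (path / f"{seg}.csv").exists()]
    if missing:
        raise FormatError(f"{path}: missing sensor file(s) for placement(s): {', '.join(missing)}")
    streams = {}
    for seg in SEGMENTS:
        f = path / f"{seg}.csv"
        df = pd.read_csv(f, float_precision="round_trip")
        if tuple(df.columns) != SENSOR_HEADER:
            raise FormatError(f"{f}: wrong header {tuple(df.columns)}, expected {SENSOR_HEADER}")
        t = df["time_s"].to_numpy(dtype=float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            row = int(np.argmax(np.diff(t) <= 0)) + 2
            raise FormatError(f"{f}: non-monotone time at row {row}")
        q = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
        norms = np.linalg.norm(q, axis=1)
        bad = np.abs(norms - 1.0) > _QNORM_TOL
        if np.any(bad):
            row = int(np.argmax(bad)) + 2
            warnings.warn(
                f"{f}: quaternion norm deviates by more than {_QNORM_TOL} "
                f"(first at row {row}); renormalizing",
                stacklevel=2,
            )
        off = np.abs(norms - 1.0) > 1e-9  # keep already-normal rows bit-stable
        if np.any(off):
            q = q.copy()
            q[off] = q[off] / norms[off, None]
        streams[seg] = OrientationStream(sensor_id=seg, t=t, q=q, fs_hz=meta.fs_hz)
    return TrialRecording(meta=meta, streams=streams)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Ground-truth kinematics CSV next to a simulated bundle."""
    path = Path(path)
    truth.as_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def write_kinematics(kin: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    kin.to_csv(path, index=False, float_format="%.17g")
    return path


def trial_dirname(meta: TrialMeta) -> str:
    load = f"{meta.load_kg:g}".replace(".", "p")
    return f"{meta.subject_id}_{meta.task}_{meta.posture}_{load}kg_r{meta.repetition}"
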