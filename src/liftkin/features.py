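"""Feature construction: task segmentation, time normalization, excursion
ranges / ranges of motion, the 10-feature trunk+lower-limb (T-Ll) and
4-feature trunk-only (UpB) sets, and z-score normalization.

One trial yields ten scalar features: the excursion range of the pelvis–trunk
displacement vector in the AP, ML and V directions (mm) and the sagittal RoM
of the lumbosacral, hip, knee and ankle joints on both sides (deg).  The UpB
subset keeps only the four trunk-related features.  Each repetition is one
sample; sub-datasets are keyed by (task, load) with both postures pooled and
the *incorrect* posture as the positive class.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .biomech import lowpass
from .errors import ConfigurationError, InputError, SegmentationError

log = logging.getLogger(__name__)

#: the ten trunk + lower-limb features, canonical order
T_LL_FEATURES = (
    "pt_ap_exc",
    "pt_ml_exc",
    "pt_v_exc",
    "rom_sacr",
    "rom_hip_l",
    "rom_hip_r",
    "rom_knee_l",
    "rom_knee_r",
    "rom_ankle_l",
    "rom_ankle_r",
)
#: the four trunk-only (upper-body) features
UPB_FEATURES = ("pt_ap_exc", "pt_ml_exc", "pt_v_exc", "rom_sacr")

FEATURE_SETS = {"T-Ll": T_LL_FEATURES, "UpB": UPB_FEATURES}

LABEL_COLUMNS = ("subject", "task", "posture", "load", "rep")

#: positive class for classification
POSITIVE_POSTURE = "incorrect"


def segment_task(
    kinematics: pd.DataFrame,
    threshold_frac: float = 0.05,
    smooth_fc_hz: float = 3.0,
    min_run: int = 3,
    markers: tuple[float, float] | None = None,
) -> tuple[int, int]:
    """Bracket the single descent–ascent cycle, returning sample indices.

    The mean hip angle is differentiated, smoothed, and the movement is taken
    to span the first to last sustained excursion of \\|velocity\\| above
    ``threshold_frac`` of its peak (a run of at least ``min_run`` samples, as
    hysteresis against noise).  Explicit ``markers`` (start, end in seconds)
    override detection and are returned verbatim.
    """
    t = kinematics["time_s"].to_numpy()
    if markers is not None:
        start_s, end_s = markers
        i0 = int(np.argmin(np.abs(t - start_s)))
        i1 = int(np.argmin(np.abs(t - end_s)))
        return i0, i1
    if len(t) < 5:
        raise InputError("kinematics series too short to segment")
    fs = 1.0 / float(np.median(np.diff(t)))
    hip = 0.5 * (kinematics["hip_l_deg"].to_numpy() + kinematics["hip_r_deg"].to_numpy())
    vel = np.gradient(hip, t)
    if smooth_fc_hz and fs > 2.0 * smooth_fc_hz:
        vel = lowpass(vel, fs, fc=smooth_fc_hz)
    speed = np.abs(vel)
    peak = float(np.max(speed))
    if peak <= 1e-9:
        raise SegmentationError("no motion above threshold in the trial")
    above = speed >= threshold_frac * peak
    # sustained runs only
    idx = np.flatnonzero(above)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    runs = [r for r in runs if r.size >= min_run]
    if not runs:
        raise SegmentationError("no sustained motion above threshold")
    start = int(runs[0][0])
    end = int(runs[-1][-1])
    if end <= start + 2:
        raise SegmentationError("detected movement window is degenerate")
    return start, end


def time_normalize(series: np.ndarray, start: int, end: int, n: int = 101) -> np.ndarray:
    """Resample ``series[start:end+1]`` to ``n`` points on 0–100% task time."""
    series = np.asarray(series, dtype=float)
    if end <= start + 2:
        raise InputError(f"degenerate window [{start}, {end}]")
    if end >= series.shape[0]:
        raise InputError("window end beyond series length")
    window = series[start : end + 1]
    src = np.linspace(0.0, 1.0, window.shape[0])
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, window)


def excursion_range(series: np.ndarray) -> float:
    """max − min; non-negative and invariant to additive constants."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise InputError("cannot take the excursion range of an empty series")
    return float(np.max(series) - np.min(series))


_CHANNEL_TO_FEATURE = {
    "pt_ap_mm": "pt_ap_exc",
    "pt_ml_mm": "pt_ml_exc",
    "pt_v_mm": "pt_v_exc",
    "sacr_deg": "rom_sacr",
    "hip_l_deg": "rom_hip_l",
    "hip_r_deg": "rom_hip_r",
    "knee_l_deg": "rom_knee_l",
    "knee_r_deg": "rom_knee_r",
    "ankle_l_deg": "rom_ankle_l",
    "ankle_r_deg": "rom_ankle_r",
}


def build_features(
    kinematics: pd.DataFrame,
    labels: dict | None = None,
    markers: tuple[float, float] | None = None,
    n_points: int = 101,
    **segment_kw,
) -> dict:
    """Ten excursion/RoM features of one trial, on the segmented,
    time-normalized window."""
    start, end = segment_task(kinematics, markers=markers, **segment_kw)
    row: dict = dict(labels or {})
    for channel, feat in _CHANNEL_TO_FEATURE.items():
        normalized = time_normalize(kinematics[channel].to_numpy(), start, end, n=n_points)
        row[feat] = excursion_range(normalized)
    return row


def feature_table(rows: list[dict]) -> pd.DataFrame:
    """Stack per-trial feature dicts into the canonical feature table."""
    df = pd.DataFrame(rows)
    cols = [c for c in LABEL_COLUMNS if c in df.columns] + list(T_LL_FEATURES)
    return df[cols]


def assemble(
    features: pd.DataFrame, feature_set: str = "T-Ll"
) -> dict[tuple[str, float], pd.DataFrame]:
    """Partition the feature table into one sub-dataset per (task, load).

    Each sub-dataset pools both postures (``n_subjects · reps · 2`` rows for a
    complete cohort) and carries the selected feature-set columns plus a
    binary ``y`` column (1 = incorrect posture).  Trials with missing feature
    values are dropped with a warning.
    """
    if feature_set not in FEATURE_SETS:
        raise ConfigurationError(f"unknown feature set {feature_set!r}")
    cols = list(FEATURE_SETS[feature_set])
    out: dict[tuple[str, float], pd.DataFrame] = {}
    n_bad = int(features[cols].isna().any(axis=1).sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} trials with missing features", stacklevel=2)
        log.warning("dropping %d trials with missing features", n_bad)
        features = features.dropna(subset=cols)
    for (task, load), group in features.groupby(["task", "load"], sort=True):
        sub = group[list(LABEL_COLUMNS) + cols].copy().reset_index(drop=True)
        sub["y"] = (sub["posture"] == POSITIVE_POSTURE).astype(int)
        out[(task, float(load))] = sub
    return out


def condition_means(features: pd.DataFrame) -> pd.DataFrame:
    """Average the repetitions: one row per subject × task × posture × load."""
    value_cols = [c for c in T_LL_FEATURES if c in features.columns]
    return (
        features.groupby(["subject", "task", "posture", "load"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )


def zscore(
    train: pd.DataFrame | np.ndarray, apply: pd.DataFrame | np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score columns by the training mean and SD (ddof=0).

    Returns ``(train_z, apply_z, mean, sd)``.  A zero-variance training
    feature raises an error naming the column.
    """
    cols = list(train.columns) if isinstance(train, pd.DataFrame) else None
    xt = np.asarray(train, dtype=float)
    xa = xt if apply is None else np.asarray(apply, dtype=float)
    mean = xt.mean(axis=0)
    sd = xt.std(axis=0)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        names = [cols[i] if cols else str(i) for i in bad]
        raise ConfigurationError(f"zero-variance feature(s) in training data: {', '.join(names)}")
    return (xt - mean) / sd, (xa - mean) / sd, mean, sd
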