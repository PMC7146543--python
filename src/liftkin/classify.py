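"""SVM posture classification per (task, load) sub-dataset: four kernels,
leave-one-out cross-validation, confusion-matrix metrics and ROC curves.

The positive class is the *incorrect* (stoop) posture.  Normalization is
leakage-safe by default: the z-scoring statistics are computed on each LOOCV
training fold and applied to the held-out sample; ``normalization="global"``
reproduces the alternative reading in which features are standardized once
before cross-validation.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .errors import ConfigurationError, InputError
from .features import FEATURE_SETS

KERNELS = ("linear", "quadratic", "cubic", "gaussian")


class PostureSVM(ClassifierMixin, BaseEstimator):
    """Support-vector classifier over kinematic features.

    A thin, sklearn-compatible estimator mapping the four kernel names used
    throughout this package onto :class:`sklearn.svm.SVC` configurations:
    ``linear``; ``quadratic``/``cubic`` = polynomial of degree 2/3 with unit
    scale and offset; ``gaussian`` = RBF with scale 1/n_features (the natural
    choice after z-scoring).  ``C`` defaults to 1.

    Parameters follow sklearn conventions (``get_params``/``set_params``), so
    the estimator composes with pipelines and model selection.
    """

    def __init__(self, kernel: str = "linear", C: float = 1.0):
        self.kernel = kernel
        self.C = C

    def _build(self, n_features: int) -> SVC:
        if self.kernel == "linear":
            return SVC(kernel="linear", C=self.C)
        if self.kernel == "quadratic":
            return SVC(kernel="poly", degree=2, gamma=1.0, coef0=1.0, C=self.C)
        if self.kernel == "cubic":
            return SVC(kernel="poly", degree=3, gamma=1.0, coef0=1.0, C=self.C)
        if self.kernel == "gaussian":
            return SVC(kernel="rbf", gamma=1.0 / n_features, C=self.C)
        raise ConfigurationError(f"unknown kernel {self.kernel!r}; choose from {KERNELS}")

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.svc_ = self._build(X.shape[1]).fit(X, y)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(X)

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(X)


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
    normalization: str = "fold",
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out predictions and decision scores.

    Each sample (or, with ``groups``, each group of samples, e.g. one subject)
    is predicted by a model trained on all the others; with
    ``normalization="fold"`` the z-scoring statistics come from the training
    fold only, so the held-out sample never influences its own scaler.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise InputError("X and y lengths differ")
    if np.unique(y).size < 2:
        raise InputError("LOOCV needs at least two classes")
    if normalization not in ("fold", "global"):
        raise ConfigurationError(f"unknown normalization mode {normalization!r}")
    if groups is None:
        groups = np.arange(X.shape[0])
    groups = np.asarray(groups)

    if normalization == "global":
        X = StandardScaler().fit_transform(X)

    y_pred = np.empty_like(y)
    scores = np.empty(X.shape[0], dtype=float)
    for g in np.unique(groups):
        test = groups == g
        train = ~test
        if np.unique(y[train]).size < 2:
            raise InputError("a training fold is single-class; dataset too small")
        xt, xe = X[train], X[test]
        if normalization == "fold":
            scaler = StandardScaler().fit(xt)
            xt, xe = scaler.transform(xt), scaler.transform(xe)
        clf = PostureSVM(kernel=kernel, C=C).fit(xt, y[train])
        y_pred[test] = clf.predict(xe)
        scores[test] = clf.decision_function(xe)
    return y_pred, scores


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts with positive = incorrect posture (label 1)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise InputError("prediction and label vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, specificity (TNR), sensitivity (TPR) and precision (PPV), %.

    Ratios with zero denominators are reported as NaN (with a warning), never
    silently 0 or 100.
    """
    return {
        "acc": _rate(c.tp + c.tn, c.n, "accuracy"),
        "tnr": _rate(c.tn, c.tn + c.fp, "specificity"),
        "tpr": _rate(c.tp, c.tp + c.fn, "sensitivity"),
        "ppv": _rate(c.tp, c.tp + c.fp, "precision"),
    }


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    optimal_point: tuple[float, float]  # (FPR, TPR) maximizing Youden's J
    degenerate: bool = False


def roc(scores: np.ndarray, y_true: np.ndarray) -> RocResult:
    """ROC curve from decision scores, with the Youden-optimal operating point."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(int)
    if not np.all(np.isfinite(scores)):
        raise InputError("decision scores must be finite")
    degenerate = bool(np.all(scores == scores[0]))
    if degenerate:
        warnings.warn("constant decision scores: degenerate single-segment ROC", stacklevel=2)
    fpr, tpr, thr = roc_curve(y_true, scores)
    j = tpr - fpr
    k = int(np.argmax(j))
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=float(sk_auc(fpr, tpr)),
        optimal_point=(float(fpr[k]), float(tpr[k])), degenerate=degenerate,
    )


def evaluate_subdataset(
    sub: pd.DataFrame,
    feature_set: str,
    kernel: str,
    C: float = 1.0,
    normalization: str = "fold",
    group_by_subject: bool = False,
) -> dict:
    """LOOCV one (task, load) sub-dataset with one kernel; full report cell."""
    cols = list(FEATURE_SETS[feature_set])
    X = sub[cols].to_numpy(dtype=float)
    y = sub["y"].to_numpy(dtype=int)
    groups = sub["subject"].to_numpy() if group_by_subject else None
    t0 = time.perf_counter()
    y_pred, scores = loocv(X, y, kernel=kernel, C=C, normalization=normalization, groups=groups)
    elapsed = time.perf_counter() - t0
    counts = confusion(y, y_pred)
    cell = {"counts": counts, "roc": roc(scores, y), "time_s": elapsed, "n": counts.n}
    cell.update(metrics(counts))
    return cell


def kernel_sweep(
    subdatasets: dict[tuple[str, float], pd.DataFrame],
    feature_sets: tuple[str, ...] = ("T-Ll", "UpB"),
    kernels: tuple[str, ...] = KERNELS,
    C: float = 1.0,
    normalization: str = "fold",
    group_by_subject: bool = False,
) -> pd.DataFrame:
    """Full report grid: task × load × feature set × kernel.

    Returns a tidy DataFrame with one row per cell (`acc`, `tnr`, `tpr`,
    `ppv`, `auc`, confusion counts, informational wall time).
    """
    rows = []
    for (task, load), sub in sorted(subdatasets.items()):
        for fset in feature_sets:
            for kernel in kernels:
                cell = evaluate_subdataset(
                    sub, fset, kernel, C=C, normalization=normalization,
                    group_by_subject=group_by_subject,
                )
                rows.append(
                    {
                        "task": task,
                        "load": load,
                        "feature_set": fset,
                        "kernel": kernel,
                        "acc": cell["acc"],
                        "tnr": cell["tnr"],
                        "tpr": cell["tpr"],
                        "ppv": cell["ppv"],
                        "auc": cell["roc"].auc,
                        "tp": cell["counts"].tp,
                        "tn": cell["counts"].tn,
                        "fp": cell["counts"].fp,
                        "fn": cell["counts"].fn,
                        "n": cell["n"],
                        "time_s": cell["time_s"],
                    }
                )
    return pd.DataFrame(rows)
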