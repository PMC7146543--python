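"""Two-way (2 posture × 3 load) repeated-measures ANOVA with Mauchly's
sphericity test, Greenhouse–Geisser correction, Bonferroni post-hoc on the
load factor, and interaction breakdown via paired t-tests.

The design is fully within-subject: every subject contributes one cell value
(the mean over repetitions) for each of the six posture × load conditions.
Sums of squares follow the standard within-subject decomposition with a
separate error stratum per effect; sphericity is assessed only for the
three-level load factor and the interaction (a two-level factor satisfies it
trivially), and the Greenhouse–Geisser degrees-of-freedom deflation is applied
when Mauchly's test is significant at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

ALPHA = 0.05


class PairedT(NamedTuple):
    t: float
    p: float
    zero_variance: bool = False


def paired_t(x: np.ndarray, y: np.ndarray) -> PairedT:
    """Paired t-test, equivalent to a one-sample t on the differences.

    Exactly constant zero differences are flagged and reported as p = 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise InputError(f"paired vectors differ in length: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise InputError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.all(d == d[0]) and d[0] == 0.0:
        return PairedT(t=0.0, p=1.0, zero_variance=True)
    t, p = sps.ttest_rel(x, y)
    return PairedT(t=float(t), p=float(p), zero_variance=False)


def bonferroni(pvals, m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m·p)."""
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    m = int(m) if m is not None else p.size
    if m < 1:
        raise InputError("number of comparisons must be >= 1")
    return np.minimum(1.0, m * p)


@dataclass
class EffectResult:
    name: str
    ss: float
    df: tuple[int, int]
    ss_error: float
    F: float
    p: float
    epsilon: float = 1.0
    p_gg: Optional[float] = None
    mauchly_w: Optional[float] = None
    mauchly_p: Optional[float] = None

    @property
    def corrected(self) -> bool:
        return self.mauchly_p is not None and self.mauchly_p < ALPHA

    @property
    def p_effective(self) -> float:
        """GG-corrected p when Mauchly's test is significant, raw p otherwise."""
        return self.p_gg if (self.corrected and self.p_gg is not None) else self.p

    def as_dict(self) -> dict:
        return {
            "effect": self.name,
            "SS": self.ss,
            "df": list(self.df),
            "SS_error": self.ss_error,
            "F": self.F,
            "p": self.p,
            "gg_epsilon": self.epsilon,
            "p_gg": self.p_gg,
            "mauchly_W": self.mauchly_w,
            "mauchly_p": self.mauchly_p,
            "p_effective": self.p_effective,
        }


@dataclass
class RmAnovaResult:
    posture: EffectResult
    weight: EffectResult
    interaction: EffectResult
    ss_subjects: float
    ss_total: float
    weight_levels: tuple
    posthoc_weight: dict = field(default_factory=dict)  # (w1, w2) -> adjusted p
    breakdown: dict = field(default_factory=dict)  # weight level -> PairedT

    def as_dict(self) -> dict:
        return {
            "effects": [e.as_dict() for e in (self.posture, self.weight, self.interaction)],
            "SS_subjects": self.ss_subjects,
            "SS_total": self.ss_total,
            "posthoc_weight_bonferroni": {f"{a}v{b}": p for (a, b), p in self.posthoc_weight.items()},
            "interaction_breakdown": {
                str(w): {"t": r.t, "p": r.p, "zero_variance": r.zero_variance}
                for w, r in self.breakdown.items()
            },
        }


def _sphericity(y: np.ndarray, n: int) -> tuple[float, float, float]:
    """Mauchly W and its p, plus the Greenhouse–Geisser epsilon.

    ``y`` is an (n_subjects, k) matrix of scores for the k repeated levels.
    """
    k = y.shape[1]
    # orthonormal contrast basis of the (k-1)-dim difference space
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    a = c.T @ np.cov(y, rowvar=False, ddof=1) @ c
    eig = np.linalg.eigvalsh(a)
    eig = np.clip(eig, 0.0, None)
    tr = float(np.sum(eig))
    if tr <= 0:
        return 1.0, 1.0, 1.0
    w = float(np.prod(eig) / (tr / (k - 1)) ** (k - 1))
    eps = float(tr**2 / ((k - 1) * np.sum(eig**2)))
    # chi-square approximation to the Mauchly statistic
    d = k - 1
    f_corr = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * np.log(max(w, 1e-300))
    df_m = d * (d + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df_m))
    return w, p, eps


def _cube_from_table(table: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    """Pivot a long table (subject, posture, weight, value) into (N, 2, k)."""
    required = {"subject", "posture", "weight", "value"}
    if not required.issubset(table.columns):
        raise InputError(f"table must have columns {sorted(required)}")
    piv = table.pivot_table(index="subject", columns=["posture", "weight"], values="value")
    postures = sorted(table["posture"].unique())
    weights = sorted(table["weight"].unique())
    expected = [(p, w) for p in postures for w in weights]
    missing = [
        f"{s}:{p}/{w}"
        for s in piv.index
        for (p, w) in expected
        if (p, w) not in piv.columns or np.isnan(piv.loc[s, (p, w)])
    ]
    if missing:
        raise InputError(f"incomplete design, missing cells: {', '.join(missing[:10])}")
    cube = np.stack([piv[(p, w)].to_numpy() for p, w in expected], axis=1)
    return cube.reshape(len(piv), len(postures), len(weights)), postures, weights


def rm_anova_2x3(
    table: pd.DataFrame | np.ndarray,
    weight_levels: tuple = (1.0, 2.0, 5.0),
    alpha: float = ALPHA,
) -> RmAnovaResult:
    """Two-way repeated-measures ANOVA on a subject × posture × weight table.

    ``table`` is either a long DataFrame (columns subject, posture, weight,
    value; cells are repetition means) or an ``(N, 2, k)`` array.  The SS
    decomposition is exact: SS_total = SS_subjects + Σ SS_effects + Σ SS_errors.
    """
    if isinstance(table, pd.DataFrame):
        cube, _postures, weights = _cube_from_table(table)
        weight_levels = tuple(weights)
    else:
        cube = np.asarray(table, dtype=float)
        if cube.ndim != 3 or cube.shape[1] != 2:
            raise InputError("cube must have shape (n_subjects, 2, k)")
    n, n_p, n_w = cube.shape
    if n < 2:
        raise InputError("need at least 2 subjects")

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_p = cube.mean(axis=(0, 2))
    m_w = cube.mean(axis=(0, 1))
    m_pw = cube.mean(axis=0)
    m_sp = cube.mean(axis=2)
    m_sw = cube.mean(axis=1)

    ss_total = float(np.sum((cube - grand) ** 2))
    ss_subj = float(n_p * n_w * np.sum((m_s - grand) ** 2))
    ss_p = float(n * n_w * np.sum((m_p - grand) ** 2))
    ss_w = float(n * n_p * np.sum((m_w - grand) ** 2))
    ss_pw = float(n * np.sum((m_pw - m_p[:, None] - m_w[None, :] + grand) ** 2))
    ss_ps = float(n_w * np.sum((m_sp - m_s[:, None] - m_p[None, :] + grand) ** 2))
    ss_ws = float(n_p * np.sum((m_sw - m_s[:, None] - m_w[None, :] + grand) ** 2))
    ss_pws = ss_total - ss_subj - ss_p - ss_w - ss_pw - ss_ps - ss_ws

    def eff(name, ss, df1, ss_err, df_err, eps=1.0, mw=None, mp=None):
        ms, ms_e = ss / df1, ss_err / df_err
        f = ms / ms_e if ms_e > 0 else np.inf
        p = float(sps.f.sf(f, df1, df_err))
        p_gg = float(sps.f.sf(f, df1 * eps, df_err * eps)) if df1 > 1 else None
        return EffectResult(
            name=name, ss=ss, df=(df1, df_err), ss_error=ss_err, F=float(f), p=p,
            epsilon=float(eps), p_gg=p_gg, mauchly_w=mw, mauchly_p=mp,
        )

    w_w, p_wm, eps_w = _sphericity(cube.mean(axis=1), n)
    diff = cube[:, 0, :] - cube[:, 1, :]
    w_i, p_im, eps_i = _sphericity(diff, n)

    posture = eff("Posture", ss_p, n_p - 1, ss_ps, n - 1)
    weight = eff("Weight", ss_w, n_w - 1, ss_ws, (n_w - 1) * (n - 1), eps_w, w_w, p_wm)
    inter = eff(
        "Posture x Weight", ss_pw, (n_p - 1) * (n_w - 1), ss_pws, (n_p - 1) * (n_w - 1) * (n - 1),
        eps_i, w_i, p_im,
    )

    # Bonferroni post-hoc between load levels (collapsed over posture)
    y_w = cube.mean(axis=1)
    pairs = [(i, j) for i in range(n_w) for j in range(i + 1, n_w)]
    raw = [paired_t(y_w[:, i], y_w[:, j]).p for i, j in pairs]
    adj = bonferroni(raw, m=len(pairs))
    posthoc = {
        (weight_levels[i], weight_levels[j]): float(a) for (i, j), a in zip(pairs, adj)
    }

    # conditional interaction breakdown: correct vs incorrect at each load
    breakdown = {}
    if inter.p_effective < alpha:
        for j in range(n_w):
            breakdown[weight_levels[j]] = paired_t(cube[:, 0, j], cube[:, 1, j])

    return RmAnovaResult(
        posture=posture,
        weight=weight,
        interaction=inter,
        ss_subjects=ss_subj,
        ss_total=ss_total,
        weight_levels=tuple(weight_levels),
        posthoc_weight=posthoc,
        breakdown=breakdown,
    )


# ---------------------------------------------------------------------------
# cohort-level reporting and simulation-based power


def anova_by_parameter(cond_means: pd.DataFrame, task: str) -> dict[str, RmAnovaResult]:
    """Run the 2×3 RM-ANOVA for every kinematic parameter of one task."""
    from .features import T_LL_FEATURES

    sub = cond_means[cond_means["task"] == task]
    out = {}
    for param in T_LL_FEATURES:
        table = sub.rename(columns={param: "value", "load": "weight"})[
            ["subject", "posture", "weight", "value"]
        ]
        out[param] = rm_anova_2x3(table)
    return out


def condition_summary(cond_means: pd.DataFrame, task: str) -> pd.DataFrame:
    """Mean ± SD of every parameter per posture × load (one task)."""
    from .features import T_LL_FEATURES

    sub = cond_means[cond_means["task"] == task]
    g = sub.groupby(["posture", "load"])[list(T_LL_FEATURES)]
    mean, sd = g.mean(), g.std(ddof=1)
    rows = []
    for (posture, load) in mean.index:
        for param in T_LL_FEATURES:
            rows.append(
                {
                    "task": task,
                    "posture": posture,
                    "load": load,
                    "parameter": param,
                    "mean": mean.loc[(posture, load), param],
                    "sd": sd.loc[(posture, load), param],
                }
            )
    return pd.DataFrame(rows)


def _draw_condition_cube(
    rng: np.random.Generator,
    n_subjects: int,
    param: str,
    task: str,
    loads: tuple[float, ...],
    repetitions: int,
    rep_jitter: float,
    hip_slope: float,
    null: bool,
    targets: dict,
) -> np.ndarray:
    """Subject × posture × load cube of repetition-mean parameters, drawn from
    the same condition distributions the trial simulator uses."""
    cube = np.empty((n_subjects, 2, len(loads)))
    sem = rep_jitter / np.sqrt(repetitions)
    for ip, posture in enumerate(("correct", "incorrect")):
        key = (task, "correct" if null else posture)
        mean, sd = targets[key][param]
        base = rng.normal(mean, sd, size=n_subjects)
        for iw, load in enumerate(loads):
            shift = hip_slope * (load - 1.0) if param == "hip" else 0.0
            cube[:, ip, iw] = base + shift + rng.normal(0.0, sem, size=n_subjects)
    return np.clip(cube, 0.0, None)


def power_check(
    param: str = "knee",
    task: str = "LL",
    n_subjects: int = 26,
    repetitions: int = 3,
    n_replicates: int = 200,
    alpha: float = ALPHA,
    seed: int = 0,
    null: bool = False,
    rep_jitter_deg: float = 3.0,
    hip_load_slope_deg_per_kg: float = 1.2,
    loads: tuple[float, ...] = (1.0, 2.0, 5.0),
    targets: dict | None = None,
) -> float:
    """Monte-Carlo rejection rate of the Posture main effect.

    Simulates at the parameter level: per replicate, each subject's
    condition-mean parameter is drawn from the cohort's condition
    distributions (plus repetition-mean noise) and the 2×3 RM-ANOVA is run.
    With ``null=True`` both postures share the correct-posture distribution,
    so the rejection rate calibrates the test's type-I error.
    """
    from .synth import CONDITION_TARGETS

    targets = targets if targets is not None else CONDITION_TARGETS
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        cube = _draw_condition_cube(
            rng, n_subjects, param, task, loads, repetitions, rep_jitter_deg,
            hip_load_slope_deg_per_kg, null, targets,
        )
        res = rm_anova_2x3(cube, weight_levels=loads)
        if res.posture.p < alpha:
            rejections += 1
    return rejections / n_replicates
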