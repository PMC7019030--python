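"""Mixed-design repeated-measures statistics for pooled translocation data.

The design is split-plot: *condition* is a between-subjects factor (each
dendrite belongs to one experimental condition), *time* is a
within-subjects factor (every dendrite is measured at every capture).  The
total corrected sum of squares is partitioned into

    between-subjects:  condition + subjects-within-condition (error 1)
    within-subjects:   time + condition×time + time×subjects (error 2)

with F ratios against the matching error stratum.  Because every subject
carries every time level, cell frequencies are proportional even when
group sizes differ, so the weighted-means decomposition below is exact and
orthogonal (total SS is conserved).

Repeated measures rarely satisfy sphericity (equal variances of all
pairwise time differences), which inflates the type-I error of the
uncorrected within-subject F tests.  The Greenhouse–Geisser correction
multiplies both degrees of freedom of the time and interaction tests by
Box's epsilon, estimated from the pooled within-group covariance of the
repeated measures:

    eps = tr(M)^2 / ((k - 1) · tr(M @ M)),   M = C S C

where S is the pooled k×k covariance and C the centering projector
I − J/k; eps is clamped to [1/(k−1), 1].  Fractional corrected dfs (e.g.
F(12.25, 211.24)) are the visible signature of this correction.

Simple main effects compare conditions at individual time points (one-way
between-condition ANOVA per time point) with Šidák adjustment
p_adj = 1 − (1 − p)^m over the m simultaneous tests.  Levene's test (ANOVA
on absolute deviations from group means) checks homogeneity of variance
across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, DesignError, ParameterError

__all__ = [
    "AnovaResult",
    "SimpleEffectsResult",
    "rm_mixed_anova",
    "rm_mixed_anova_matrix",
    "gg_epsilon",
    "sidak_adjust",
    "simple_effects",
    "levene_test",
    "format_effect",
]


@dataclass
class AnovaResult:
    """Split-plot ANOVA effects table plus the sphericity correction.

    ``table`` rows: condition, subject_error, time, condition_x_time,
    time_error — with columns ss, df, df_gg (within-subject rows only),
    ms, F, p, p_gg.  ``epsilon`` is Box's epsilon from the pooled
    within-subject covariance.
    """

    table: pd.DataFrame
    epsilon: float
    n_subjects: int
    n_conditions: int
    n_times: int

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def interaction_p(self) -> float:
        """GG-corrected p value of the condition×time interaction."""
        return float(self.table.loc["condition_x_time", "p_gg"])


@dataclass
class SimpleEffectsResult:
    """Per-time-point between-condition tests with Šidák adjustment.

    ``omnibus``: one row per time point (F, df1, df2, p, p_sidak,
    significant).  ``pairwise``: condition-pair t contrasts per time
    point, Šidák-adjusted over the pairs within that time point.
    """

    omnibus: pd.DataFrame
    pairwise: pd.DataFrame
    alpha: float
    m_tests: int


def _pivot_design(table: pd.DataFrame, dv: str, within: str, subject: str, between: str):
    """Wide (subjects × times) response matrix plus group labels.

    Raises :class:`DesignError` on any imbalance — no silent imputation.
    """
    for col in (dv, within, subject, between):
        if col not in table.columns:
            raise ParameterError(f"column {col!r} missing from the table")
    counts = table.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index[0]
        raise DesignError(f"unbalanced design: subject/time cell {bad} has {counts.max()} rows")
    wide = table.pivot(index=subject, columns=within, values=dv).sort_index()
    wide = wide[sorted(wide.columns)]
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()][0]
        raise DesignError(f"unbalanced design: missing observations at {within}={missing}")
    subj_cond = table.drop_duplicates(subject).set_index(subject)[between]
    groups = subj_cond.reindex(wide.index).to_numpy()
    return wide.to_numpy(dtype=float), groups, list(wide.columns)


def _mixed_anova_arrays(Y: np.ndarray, groups: np.ndarray) -> dict:
    """Split-plot SS decomposition on a (subjects × times) matrix.

    Returns sums of squares, dfs, F statistics and the pooled
    within-group covariance; no p values (callers attach them).
    """
    N, k = Y.shape
    labels, inv = np.unique(groups, return_inverse=True)
    G = labels.size
    n_g = np.bincount(inv)
    if G < 2:
        raise DesignError("need >= 2 conditions")
    if k < 2:
        raise DesignError("need >= 2 time levels")
    if np.any(n_g < 2):
        raise DesignError("need >= 2 subjects per condition")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    time_means = Y.mean(axis=0)
    group_means = np.array([Y[inv == g].mean() for g in range(G)])
    cell_means = np.vstack([Y[inv == g].mean(axis=0) for g in range(G)])  # G × k

    ss_total = float(((Y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_cond = float(k * (n_g * (group_means - grand) ** 2).sum())
    ss_subj = ss_between_subj - ss_cond
    ss_time = float(N * ((time_means - grand) ** 2).sum())
    ss_inter = float(
        (n_g[:, None] * (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2).sum()
    )
    ss_err = ss_total - ss_between_subj - ss_time - ss_inter

    df_cond, df_subj = G - 1, N - G
    df_time = k - 1
    df_inter = (G - 1) * (k - 1)
    df_err = (N - G) * (k - 1)

    # pooled within-group covariance of the repeated measures
    resid = Y - cell_means[inv]
    if N - G < 1:
        raise DesignError("no residual df for the within-subject covariance")
    S = resid.T @ resid / (N - G)

    def _F(ss_eff: float, df_eff: int, ss_e: float, df_e: int) -> float:
        ms_e = ss_e / df_e
        if ms_e <= 0:
            return 0.0 if ss_eff <= 1e-300 else np.inf
        return (ss_eff / df_eff) / ms_e

    return {
        "ss": {
            "condition": ss_cond, "subject_error": ss_subj, "time": ss_time,
            "condition_x_time": ss_inter, "time_error": ss_err, "total": ss_total,
        },
        "df": {
            "condition": df_cond, "subject_error": df_subj, "time": df_time,
            "condition_x_time": df_inter, "time_error": df_err,
        },
        "F": {
            "condition": _F(ss_cond, df_cond, ss_subj, df_subj),
            "time": _F(ss_time, df_time, ss_err, df_err),
            "condition_x_time": _F(ss_inter, df_inter, ss_err, df_err),
        },
        "cov": S,
        "shape": (N, G, k),
    }


def gg_epsilon(within_cov: np.ndarray) -> float:
    """Box's epsilon from a k×k covariance of repeated measures.

    Double-centers the covariance and evaluates
    tr(M)² / ((k−1)·tr(M²)); the result is clamped to [1/(k−1), 1].
    Equals 1 exactly for k = 2 and for any compound-symmetric covariance
    (sphericity holds); approaches 1/(k−1) under maximal violation.
    """
    S = np.asarray(within_cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 2:
        raise ParameterError("within_cov must be a square k x k matrix, k >= 2")
    if not np.allclose(S, S.T, rtol=1e-8, atol=1e-8):
        raise ParameterError("within_cov must be symmetric")
    k = S.shape[0]
    C = np.eye(k) - np.full((k, k), 1.0 / k)
    M = C @ S @ C
    denom = (k - 1) * float((M * M).sum())
    if denom <= 0:
        raise DegenerateInputError("within-subject covariance is singular after centering")
    eps = float(np.trace(M)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _epsilon_or_one(cov: np.ndarray) -> float:
    """GG epsilon; a zero centered covariance (no within-subject residual
    variation at all) trivially satisfies sphericity, so return 1."""
    k = cov.shape[0]
    C = np.eye(k) - np.full((k, k), 1.0 / k)
    M = C @ cov @ C
    if float((M * M).sum()) == 0.0:
        return 1.0
    return gg_epsilon(cov)


def _attach_p(res: dict, epsilon: float) -> pd.DataFrame:
    ss, df, F = res["ss"], res["df"], res["F"]
    rows = []
    for name in ("condition", "subject_error", "time", "condition_x_time", "time_error"):
        row = {"ss": ss[name], "df": df[name], "ms": ss[name] / df[name]}
        if name == "condition":
            row["F"] = F[name]
            row["p"] = float(sps.f.sf(F[name], df["condition"], df["subject_error"]))
            row["p_gg"] = row["p"]  # between-subjects test is not corrected
            row["df_gg"] = float(df[name])
        elif name in ("time", "condition_x_time"):
            row["F"] = F[name]
            row["p"] = float(sps.f.sf(F[name], df[name], df["time_error"]))
            row["df_gg"] = epsilon * df[name]
            row["p_gg"] = float(sps.f.sf(F[name], epsilon * df[name], epsilon * df["time_error"]))
        else:
            row["F"] = np.nan
            row["p"] = np.nan
            row["p_gg"] = np.nan
            row["df_gg"] = float(df[name])
        rows.append(row)
    out = pd.DataFrame(
        rows,
        index=["condition", "subject_error", "time", "condition_x_time", "time_error"],
        columns=["ss", "df", "df_gg", "ms", "F", "p", "p_gg"],
    )
    # F = 0/0 cases (no variation at all): report F = 0, p = 1
    out.loc[out["F"] == 0.0, "p"] = 1.0
    out.loc[out["F"] == 0.0, "p_gg"] = 1.0
    return out


def rm_mixed_anova_matrix(Y: np.ndarray, groups: np.ndarray) -> AnovaResult:
    """Mixed ANOVA straight from a (subjects × times) matrix.

    Fast path for Monte Carlo calibration; identical decomposition to
    :func:`rm_mixed_anova`, skipping the long-table pivot.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    if Y.ndim != 2 or groups.shape != (Y.shape[0],):
        raise ParameterError("Y must be (subjects x times) with one group label per row")
    res = _mixed_anova_arrays(Y, groups)
    eps = _epsilon_or_one(res["cov"])
    N, G, k = res["shape"]
    return AnovaResult(table=_attach_p(res, eps), epsilon=eps,
                       n_subjects=N, n_conditions=G, n_times=k)


def rm_mixed_anova(
    table: pd.DataFrame,
    dv: str = "rel_fluor",
    within: str = "time_s",
    subject: str = "dendrite_id",
    between: str = "condition",
) -> AnovaResult:
    """Mixed-design repeated-measures ANOVA with Greenhouse–Geisser correction.

    Requires a balanced within-subject design (every subject at every time
    level exactly once), at least two conditions, two time levels and two
    subjects per condition.  Within-subject p values (``p_gg``) use
    epsilon-corrected fractional dfs; the between-subjects condition test
    is unaffected by sphericity and is reported uncorrected.
    """
    Y, groups, _ = _pivot_design(table, dv, within, subject, between)
    res = _mixed_anova_arrays(Y, groups)
    eps = _epsilon_or_one(res["cov"])
    N, G, k = res["shape"]
    return AnovaResult(
        table=_attach_p(res, eps),
        epsilon=eps,
        n_subjects=N,
        n_conditions=G,
        n_times=k,
    )


def sidak_adjust(p: float | np.ndarray, m: int) -> np.ndarray:
    """Šidák multiplicity adjustment: p_adj = 1 − (1 − p)^m."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p values must lie in [0, 1]")
    return -np.expm1(m * np.log1p(-p))


def simple_effects(
    table: pd.DataFrame,
    timepoints: Sequence[float],
    alpha: float = 0.05,
    dv: str = "rel_fluor",
    within: str = "time_s",
    between: str = "condition",
) -> SimpleEffectsResult:
    """Between-condition tests at chosen time points, Šidák-adjusted.

    At each requested time point a one-way between-condition ANOVA is run
    on that time point's own error term; omnibus p values are adjusted
    over the ``m = len(timepoints)`` simultaneous tests.  Pairwise pooled-
    variance t contrasts are reported per time point, adjusted over the
    number of pairs within that time point.
    """
    available = set(table[within].unique())
    missing = [t for t in timepoints if t not in available]
    if missing:
        raise ParameterError(f"time points {missing} not present in the table")
    m = len(timepoints)
    omnibus_rows, pair_rows = [], []
    for t in timepoints:
        sub = table[table[within] == t]
        conds = sorted(sub[between].unique())
        samples = [sub.loc[sub[between] == c, dv].to_numpy() for c in conds]
        if len(samples) < 2:
            raise DesignError("need >= 2 conditions for simple effects")
        F, p = sps.f_oneway(*samples)
        df1 = len(samples) - 1
        df2 = sum(len(s) for s in samples) - len(samples)
        p_adj = float(sidak_adjust(p, m))
        omnibus_rows.append(
            {
                "time_s": t, "F": float(F), "df1": df1, "df2": df2,
                "p": float(p), "p_sidak": p_adj, "significant": p_adj < alpha,
            }
        )
        pairs = list(combinations(range(len(conds)), 2))
        for i, j in pairs:
            tt = sps.ttest_ind(samples[i], samples[j], equal_var=True)
            p_pair = float(sidak_adjust(tt.pvalue, len(pairs)))
            pair_rows.append(
                {
                    "time_s": t, "condition_a": conds[i], "condition_b": conds[j],
                    "t": float(tt.statistic),
                    "df": len(samples[i]) + len(samples[j]) - 2,
                    "p": float(tt.pvalue), "p_sidak": p_pair,
                    "significant": p_pair < alpha,
                }
            )
    return SimpleEffectsResult(
        omnibus=pd.DataFrame(omnibus_rows),
        pairwise=pd.DataFrame(pair_rows),
        alpha=alpha,
        m_tests=m,
    )


def levene_test(
    table: pd.DataFrame,
    at_time: float | None = None,
    dv: str = "rel_fluor",
    within: str = "time_s",
    between: str = "condition",
) -> tuple[float, tuple[int, int], float]:
    """Classic Levene's test of equal group variances.

    One-way ANOVA on absolute deviations from the group means
    (``center='mean'``, the original Levene statistic).  With
    ``at_time=None`` all observations are pooled over time per condition;
    otherwise only the chosen time point is tested.

    Returns ``(W, (df1, df2), p)``.
    """
    sub = table if at_time is None else table[table[within] == at_time]
    if at_time is not None and sub.empty:
        raise ParameterError(f"time point {at_time} not present in the table")
    groups = [g[dv].to_numpy() for _, g in sub.groupby(between)]
    if len(groups) < 2:
        raise DesignError("need >= 2 conditions")
    if any(len(g) < 2 for g in groups):
        raise DesignError("every condition needs >= 2 observations")
    with np.errstate(invalid="ignore"):
        W, p = sps.levene(*groups, center="mean")
    if np.isnan(W):
        # identical absolute deviations in every group: no spread difference
        devs = np.concatenate([np.abs(g - g.mean()) for g in groups])
        if np.allclose(devs, devs[0]):
            W, p = 0.0, 1.0
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(W), (df1, df2), float(p)


def format_effect(result: AnovaResult, name: str, corrected: bool = True) -> str:
    """Render one effect as ``F(df1, df2) = x.xx, p = ...`` (GG dfs at 2 dp)."""
    row = result.table.loc[name]
    if name == "condition":
        df1, df2 = row["df"], result.table.loc["subject_error", "df"]
        p = row["p"]
    else:
        eps = result.epsilon if corrected else 1.0
        df1 = row["df"] * eps
        df2 = result.table.loc["time_error", "df"] * eps
        p = row["p_gg"] if corrected else row["p"]
    ptxt = f"p = {p:.4f}" if p >= 1e-4 else "p < 0.0001"
    return f"F({df1:.2f}, {df2:.2f}) = {row['F']:.2f}, {ptxt}"
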