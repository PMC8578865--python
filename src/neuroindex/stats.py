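"""Longitudinal inferential statistics computed from first principles.

Implements the inference used throughout the analysis: Pearson correlation
with its t-based two-tailed significance, one-way repeated-measures ANOVA
with the Greenhouse-Geisser sphericity correction and paired post-hoc
contrasts against baseline, the two-way mixed (split-plot) drug x time ANOVA,
and Welch's two-sample t test.  Sums of squares, F ratios and the epsilon
estimator are computed directly from their definitions; only the t and F
tail probabilities come from :mod:`scipy.stats`.

All p values are two-tailed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats as sps


# --------------------------------------------------------------------------
# Pearson correlation
# --------------------------------------------------------------------------

@dataclasses.dataclass
class CorrelationResult:
    """Pearson r with R^2, the t statistic on n-2 df, and its two-tailed p."""

    r: float
    r_squared: float
    t_stat: float
    df: int
    p_two_tailed: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with t-distribution significance.

    r = sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) sum((y-ybar)^2)),
    t = r sqrt((n-2) / (1-r^2)), p two-tailed from Student's t with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(xd @ yd) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(r=r, r_squared=r * r, t_stat=float(t), df=df,
                             p_two_tailed=float(p), n=n)


# --------------------------------------------------------------------------
# t tests
# --------------------------------------------------------------------------

@dataclasses.dataclass
class TTestResult:
    t_stat: float
    df: float
    p_two_tailed: float
    n: tuple[int, ...]


def paired_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Paired t test: t = dbar / (sd / sqrt(n)) on the differences a - b.

    Zero-variance differences degenerate: t = 0, p = 1 for identical pairs,
    t = +/-inf, p = 0 for a constant nonzero shift.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, n - 1, 1.0, (n,))
        return TTestResult(float(np.sign(mean)) * np.inf, n - 1, 0.0, (n,))
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TTestResult(float(t), n - 1, float(p), (n,))


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance t test with Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, na + nb - 2, 1.0, (na, nb))
        return TTestResult(float(np.sign(diff)) * np.inf, na + nb - 2, 0.0, (na, nb))
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), (na, nb))


# --------------------------------------------------------------------------
# ANOVA machinery
# --------------------------------------------------------------------------

@dataclasses.dataclass
class AnovaEffect:
    """One tested effect: raw and epsilon-corrected df, F, and p values.

    ``p`` is the headline p value: Greenhouse-Geisser corrected for within-
    subject effects when a correction was applied, the uncorrected value
    otherwise.
    """

    name: str
    ss: float
    df: tuple[float, float]
    ms: float
    f_stat: float
    p_uncorrected: float
    epsilon: float | None = None
    df_corrected: tuple[float, float] | None = None
    p: float = float("nan")


@dataclasses.dataclass
class PairedContrast:
    """Post-hoc paired contrast of one visit day against baseline."""

    level: int
    t_stat: float
    df: int
    p_raw: float
    p_adjusted: float


@dataclasses.dataclass
class AnovaResult:
    effects: list[AnovaEffect]
    components: dict[str, tuple[float, float]]  # error/stratum name -> (ss, df)
    ss_total: float
    n_subjects: int
    posthoc: list[PairedContrast] | None = None

    def effect(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in self.effects:
            rows.append(
                {
                    "effect": e.name, "ss": e.ss, "df1": e.df[0], "df2": e.df[1],
                    "epsilon": e.epsilon,
                    "df1_corrected": e.df_corrected[0] if e.df_corrected else None,
                    "df2_corrected": e.df_corrected[1] if e.df_corrected else None,
                    "F": e.f_stat, "p": e.p,
                }
            )
        for name, (ss, df) in self.components.items():
            rows.append({"effect": name, "ss": ss, "df1": df, "df2": None,
                         "epsilon": None, "df1_corrected": None,
                         "df2_corrected": None, "F": None, "p": None})
        return pd.DataFrame(rows)


def _f_p(f: float, df1: float, df2: float) -> float:
    if not np.isfinite(f):
        return 0.0
    if df1 <= 0 or df2 <= 0:
        return float("nan")
    return float(sps.f.sf(f, df1, df2))


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from a conditions covariance matrix.

    With S~ the double-centered sample covariance of the k within-subject
    conditions, epsilon = tr(S~)^2 / ((k-1) * sum(S~_ij^2)), bounded in
    [1/(k-1), 1]; equals 1 exactly under compound symmetry and for k = 2.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, rtol=1e-10, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least 2 conditions")
    C = np.eye(k) - np.full((k, k), 1.0 / k)
    St = C @ S @ C
    denom = (k - 1) * float(np.sum(St * St))
    if denom == 0.0:
        return 1.0
    eps = float(np.trace(St)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _check_matrix(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a subjects x conditions matrix")
    if np.isnan(data).any():
        raise ValueError("missing cells; complete-case the matrix first")
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    return data


def rm_anova_oneway(data: np.ndarray, correction: bool = True) -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions matrix.

    Partitions the total sum of squares into subjects, conditions (time) and
    error strata; F = MS_time / MS_error on (k-1, (n-1)(k-1)) df.  When
    ``correction`` is on, the Greenhouse-Geisser epsilon estimated from the
    sample covariance of the conditions multiplies both df for the headline p.
    """
    data = _check_matrix(data)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_subjects = float(k * ((row_means - grand) ** 2).sum())
    ss_time = float(n * ((col_means - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_time
    ss_error = max(ss_error, 0.0)
    df_time = k - 1
    df_error = (n - 1) * (k - 1)
    # numerical zero: sums of squares below float residue of the total
    tol = 1e-12 * (ss_total + 1.0)
    ss_time = 0.0 if ss_time < tol else ss_time
    ss_error = 0.0 if ss_error < tol else ss_error
    ms_time = ss_time / df_time
    ms_error = ss_error / df_error
    if ss_time == 0.0:
        f = 0.0
        p_unc = 1.0
    elif ms_error == 0.0:
        f = float("inf")
        p_unc = 0.0
    else:
        f = ms_time / ms_error
        p_unc = _f_p(f, df_time, df_error)
    effect = AnovaEffect(
        name="time", ss=ss_time, df=(df_time, df_error), ms=ms_time,
        f_stat=float(f), p_uncorrected=p_unc, p=p_unc,
    )
    if correction:
        eps = gg_epsilon(np.cov(data, rowvar=False, ddof=1))
        effect.epsilon = eps
        effect.df_corrected = (eps * df_time, eps * df_error)
        if ss_time == 0.0:
            effect.p = 1.0
        elif ms_error == 0.0:
            effect.p = 0.0
        else:
            effect.p = _f_p(f, *effect.df_corrected)
    return AnovaResult(
        effects=[effect],
        components={"subjects": (ss_subjects, n - 1), "error": (ss_error, df_error)},
        ss_total=ss_total,
        n_subjects=n,
    )


def posthoc_vs_baseline(
    data: np.ndarray, baseline_index: int = 0, correction: str = "none"
) -> list[PairedContrast]:
    """Paired t of every non-baseline condition against the baseline column.

    ``correction`` is ``"none"`` (p_adjusted = p_raw) or ``"bonferroni"``
    (p multiplied by the number of contrasts, clipped at 1).
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError("correction must be 'none' or 'bonferroni'")
    data = _check_matrix(data)
    k = data.shape[1]
    base = data[:, baseline_index]
    m = k - 1
    out = []
    for j in range(k):
        if j == baseline_index:
            continue
        res = paired_t(data[:, j], base)
        p_adj = res.p_two_tailed if correction == "none" else min(1.0, m * res.p_two_tailed)
        out.append(PairedContrast(level=j, t_stat=res.t_stat, df=int(res.df),
                                  p_raw=res.p_two_tailed, p_adjusted=p_adj))
    return out


def mixed_anova(
    data: np.ndarray, group: Sequence, correction: bool = True
) -> AnovaResult:
    """Two-way mixed (split-plot) ANOVA: between-subjects group, within time.

    The between stratum splits into the group effect (tested against subjects
    within groups) and the within stratum into time and group x time (tested
    against the subject x time residual).  The Greenhouse-Geisser epsilon is
    estimated from the pooled within-group covariance of the conditions and
    applied to both within-subject effects.  With unequal group sizes the
    decomposition uses group-size-weighted (sequential) sums of squares;
    components always add up to the total sum of squares.
    """
    data = _check_matrix(data)
    group = np.asarray(group)
    n, k = data.shape
    if group.shape != (n,):
        raise ValueError("group must give one label per subject")
    levels = list(dict.fromkeys(group.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {g: int((group == g).sum()) for g in levels}
    if min(sizes.values()) < 2:
        raise ValueError("every group needs at least 2 subjects")

    grand = data.mean()
    subj_means = data.mean(axis=1)
    time_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())

    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(
        k * sum(sizes[g] * (subj_means[group == g].mean() - grand) ** 2 for g in levels)
    )
    ss_subj_within = max(ss_between_subj - ss_group, 0.0)

    ss_time = float(n * ((time_means - grand) ** 2).sum())
    ss_cells = float(
        sum(
            sizes[g] * ((data[group == g].mean(axis=0) - grand) ** 2).sum()
            for g in levels
        )
    )
    ss_inter = max(ss_cells - ss_group - ss_time, 0.0)
    ss_within_total = ss_total - ss_between_subj
    ss_error_within = max(ss_within_total - ss_time - ss_inter, 0.0)

    g_n = len(levels)
    df_group = g_n - 1
    df_subj_within = n - g_n
    df_time = k - 1
    df_inter = df_group * df_time
    df_error_within = df_subj_within * df_time

    tol = 1e-12 * (ss_total + 1.0)
    ss_group = 0.0 if ss_group < tol else ss_group
    ss_inter = 0.0 if ss_inter < tol else ss_inter
    ss_time = 0.0 if ss_time < tol else ss_time
    ss_subj_within = 0.0 if ss_subj_within < tol else ss_subj_within
    ss_error_within = 0.0 if ss_error_within < tol else ss_error_within

    ms_sw = ss_subj_within / df_subj_within
    ms_ew = ss_error_within / df_error_within

    def make_effect(name, ss, df1, df2, ms_err):
        ms = ss / df1
        if ss == 0.0:
            f, p = 0.0, 1.0
        elif ms_err == 0.0:
            f, p = float("inf"), 0.0
        else:
            f = ms / ms_err
            p = _f_p(f, df1, df2)
        return AnovaEffect(name=name, ss=ss, df=(df1, df2), ms=ms,
                           f_stat=float(f), p_uncorrected=p, p=p)

    eff_group = make_effect("drug", ss_group, df_group, df_subj_within, ms_sw)
    eff_time = make_effect("time", ss_time, df_time, df_error_within, ms_ew)
    eff_inter = make_effect("drug:time", ss_inter, df_inter, df_error_within, ms_ew)

    if correction:
        pooled = np.zeros((k, k))
        for g in levels:
            pooled += (sizes[g] - 1) * np.cov(data[group == g], rowvar=False, ddof=1)
        pooled /= n - g_n
        eps = gg_epsilon(pooled)
        for eff in (eff_time, eff_inter):
            eff.epsilon = eps
            eff.df_corrected = (eps * eff.df[0], eps * eff.df[1])
            if eff.ss == 0.0:
                eff.p = 1.0
            elif ms_ew == 0.0:
                eff.p = 0.0
            else:
                eff.p = _f_p(eff.f_stat, *eff.df_corrected)

    return AnovaResult(
        effects=[eff_group, eff_time, eff_inter],
        components={
            "subjects_within_groups": (ss_subj_within, df_subj_within),
            "error_within": (ss_error_within, df_error_within),
        },
        ss_total=ss_total,
        n_subjects=n,
    )
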