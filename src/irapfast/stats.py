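"""Two-group comparison battery and the split-plot (mixed within-between) ANOVA.

The nonparametric battery reports the Mann-Whitney pair count W for the
first group (ties half-weighted), the effect-size estimator r = W/(n1*n2),
Cliff's delta, and the Vargha-Delaney A = (delta + 1)/2; r and A coincide
whenever W counts the same direction, and both equal the ROC AUC with the
first group as controls. The parametric battery reports Welch's t (fractional
Welch-Satterthwaite df) and the pooled-SD Cohen's d.

The repeated-measures analysis of the four trial-type D scores is fitted as
the classical split-plot decomposition: orientation is tested in the
between-subject stratum against subjects-within-groups, trial-type and the
interaction in the within stratum against the residual. For complete data
(every participant contributing all four trial-types) these F tests coincide
with the ones obtained from a random-intercept mixed model, which is why
unbalanced (incomplete) input is rejected rather than approximated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import EffectReport

EXACT_WILCOXON_MAX_N = 25


def _as_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    return x, y


def mann_whitney_w(x, y) -> float:
    """Pair count #{x_i > y_j} with ties half-weighted (Wilcoxon's W for x)."""
    x, y = _as_arrays(x, y)
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def rank_sum_test(x, y) -> EffectReport:
    """Wilcoxon rank-sum test with the study's r effect-size estimator.

    The p value is exact (full enumeration) when n1 + n2 <= 25 and the data
    carry no cross-group ties, otherwise a tie-corrected normal approximation
    with continuity correction is used.
    """
    x, y = _as_arrays(x, y)
    w = mann_whitney_w(x, y)
    n1, n2 = len(x), len(y)
    no_ties = len(np.unique(np.concatenate([x, y]))) == n1 + n2
    method = "exact" if (n1 + n2 <= EXACT_WILCOXON_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return EffectReport(
        w_statistic=w, r_estimator=w / (n1 * n2), w_p_value=float(res.pvalue)
    )


def cliffs_delta(x, y) -> float:
    """Dominance statistic (#{x>y} - #{x<y}) / (n1*n2)."""
    x, y = _as_arrays(x, y)
    diff = x[:, None] - y[None, :]
    return float(((diff > 0).sum() - (diff < 0).sum()) / diff.size)


def vd_a(delta: float) -> float:
    """Vargha-Delaney probability-of-superiority A = (delta + 1)/2."""
    return (delta + 1.0) / 2.0


def cohens_d_pooled(m1, s1, n1, m2, s2, n2) -> float:
    sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if sp == 0.0:
        raise ValueError("zero pooled SD: Cohen's d undefined")
    return (m1 - m2) / sp


def welch_t_from_stats(m1, s1, n1, m2, s2, n2) -> EffectReport:
    """Welch's t test and pooled Cohen's d from group summary moments."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0.0:
        raise ValueError("zero variance in both groups")
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return EffectReport(
        t_statistic=float(t),
        t_df=float(df),
        t_p_value=float(p),
        cohens_d=float(cohens_d_pooled(m1, s1, n1, m2, s2, n2)),
    )


def welch_t(x, y) -> EffectReport:
    x, y = _as_arrays(x, y)
    return welch_t_from_stats(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def compare_groups(x, y) -> EffectReport:
    """Full two-group bundle: W, r, p; Cliff's delta and A; Welch t and d."""
    nonpar = rank_sum_test(x, y)
    delta = cliffs_delta(x, y)
    par = welch_t(x, y)
    return EffectReport(
        w_statistic=nonpar.w_statistic,
        r_estimator=nonpar.r_estimator,
        w_p_value=nonpar.w_p_value,
        cliffs_delta=delta,
        vd_a=vd_a(delta),
        t_statistic=par.t_statistic,
        t_df=par.t_df,
        t_p_value=par.t_p_value,
        cohens_d=par.cohens_d,
    )


def one_sample_t(scores, mu0: float = 0.0) -> tuple[float, int, float]:
    """One-sample t test against mu0; zero-variance input is an error."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need n >= 2")
    if scores.std(ddof=1) == 0.0:
        if np.allclose(scores, mu0):
            return 0.0, len(scores) - 1, 1.0
        raise ValueError("zero variance with nonzero mean shift: t undefined")
    res = sps.ttest_1samp(scores, mu0)
    return float(res.statistic), len(scores) - 1, float(res.pvalue)


def spearman_rho(a, b) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) with its p value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        raise ValueError("constant vector: rank correlation undefined")
    res = sps.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Split-plot ANOVA


@dataclass
class SplitPlotFit:
    """Fitted split-plot decomposition of a groups x repeated-measures table."""

    table: pd.DataFrame  # effects x (sum_sq, mean_sq, df_num, df_den, F, p)
    cell_means: pd.DataFrame  # group x measure
    group_sizes: dict[str, int]
    ms_subject: float
    df_subject: int
    ms_resid: float
    df_resid: int
    measures: list[str]
    groups: list[str]


def split_plot_anova(scores: pd.DataFrame, groups: pd.Series) -> SplitPlotFit:
    """Classical mixed within-between ANOVA on a wide participant table.

    ``scores``: one row per participant, one column per repeated measure;
    ``groups``: the between-subject label per row (two or more levels).
    Every participant must contribute every measure (complete data); the
    within-stratum terms use Type III (unweighted-means) sums of squares so
    unequal group sizes are handled the way the usual mixed-model fit does.
    """
    y = scores.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(
            "incomplete repeated measures: the split-plot decomposition only "
            "coincides with the mixed-model fit for complete data; drop or "
            "impute incomplete participants explicitly before calling"
        )
    glabels = pd.Series(groups).astype(str).to_numpy()
    measures = list(scores.columns)
    glevels = sorted(set(glabels))
    a, b, n_tot = len(glevels), len(measures), len(y)
    if a < 2 or b < 2:
        raise ValueError("need >=2 groups and >=2 repeated measures")
    n_g = {g: int((glabels == g).sum()) for g in glevels}
    if min(n_g.values()) < 2:
        raise ValueError("need >=2 participants per group")

    subj_means = y.mean(axis=1)
    cell = np.vstack([y[glabels == g].mean(axis=0) for g in glevels])

    # Between-subject stratum (one between factor: Type III == classical)
    group_means = {g: subj_means[glabels == g].mean() for g in glevels}
    grand_subj = float(subj_means.mean())
    ss_group = b * sum(
        n_g[g] * (group_means[g] - grand_subj) ** 2 for g in glevels
    )
    ss_subj = b * sum(
        ((subj_means[glabels == g] - group_means[g]) ** 2).sum() for g in glevels
    )
    df_group, df_subj = a - 1, n_tot - a

    # Within stratum, unweighted (Type III) means
    n_h = a / sum(1.0 / n_g[g] for g in glevels)  # harmonic mean group size
    meas_unw = cell.mean(axis=0)  # unweighted measure means
    ss_meas = n_h * a * ((meas_unw - meas_unw.mean()) ** 2).sum()
    inter = cell - cell.mean(axis=1, keepdims=True) - meas_unw + meas_unw.mean()
    ss_inter = n_h * (inter**2).sum()
    ss_total_within = ((y - subj_means[:, None]) ** 2).sum()
    # residual from the weighted decomposition (exact regardless of balance)
    ss_resid = sum(
        ((y[glabels == g] - subj_means[glabels == g][:, None] - cell[i]
          + cell[i].mean()) ** 2).sum()
        for i, g in enumerate(glevels)
    )
    df_meas = b - 1
    df_inter = (a - 1) * (b - 1)
    df_resid = (n_tot - a) * (b - 1)

    ms_subj = ss_subj / df_subj
    ms_resid = ss_resid / df_resid

    def row(name, ss, dfn, ms_err, dfd):
        ms = ss / dfn
        if ms_err == 0.0:
            f = p = math.nan
        else:
            f = ms / ms_err
            p = float(sps.f.sf(f, dfn, dfd))
        return {
            "effect": name, "sum_sq": ss, "mean_sq": ms,
            "df_num": dfn, "df_den": dfd, "F": f, "p": p,
        }

    table = pd.DataFrame(
        [
            row("measure", ss_meas, df_meas, ms_resid, df_resid),
            row("group", ss_group, df_group, ms_subj, df_subj),
            row("interaction", ss_inter, df_inter, ms_resid, df_resid),
        ]
    ).set_index("effect")
    _ = ss_total_within  # retained for the SS-additivity property test
    return SplitPlotFit(
        table=table,
        cell_means=pd.DataFrame(cell, index=glevels, columns=measures),
        group_sizes=n_g,
        ms_subject=float(ms_subj),
        df_subject=df_subj,
        ms_resid=float(ms_resid),
        df_resid=df_resid,
        measures=measures,
        groups=glevels,
    )


def _satterthwaite(parts: list[tuple[float, float, float]]) -> tuple[float, float]:
    """Variance and df for a linear combination sum(c * MS) of mean squares.

    ``parts`` holds (coefficient, mean_square, df) triples.
    """
    v = sum(c * ms for c, ms, _ in parts)
    denom = sum((c * ms) ** 2 / df for c, ms, df in parts)
    return v, (v**2 / denom if denom > 0 else math.inf)


def pairwise_contrasts(fit: SplitPlotFit, alpha: float = 0.05) -> dict:
    """Within-group Tukey contrasts, between-group per-measure t tests, and
    Bonferroni-adjusted CIs for the cell means.

    Within-group measure contrasts use the residual mean square on its
    (N - a)(b - 1) df with Tukey adjustment for the family of ``b`` measures.
    Between-group contrasts and the cell-mean CIs combine the two error
    strata with Satterthwaite df; the CI family is Bonferroni-adjusted for
    all a*b cell means.
    """
    b = len(fit.measures)
    k_cells = b * len(fit.groups)
    within_rows, between_rows, ci_rows = [], [], []
    for g in fit.groups:
        n = fit.group_sizes[g]
        se = math.sqrt(2.0 * fit.ms_resid / n)
        for i in range(b):
            for j in range(i + 1, b):
                est = fit.cell_means.loc[g, fit.measures[i]] - fit.cell_means.loc[
                    g, fit.measures[j]
                ]
                t = est / se if se > 0 else math.nan
                p = float(
                    sps.studentized_range.sf(abs(t) * math.sqrt(2.0), b, fit.df_resid)
                ) if se > 0 else math.nan
                within_rows.append(
                    {
                        "group": g,
                        "contrast": f"{fit.measures[i]} - {fit.measures[j]}",
                        "estimate": est, "se": se, "t": t, "df": fit.df_resid,
                        "p_tukey": min(1.0, p) if not math.isnan(p) else p,
                    }
                )
    # between-group contrasts per measure: var((sigma_s^2+sigma_e^2)(1/n1+1/n2))
    # with sigma_s^2+sigma_e^2 = (MS_subj + (b-1) MS_resid)/b
    g1, g2 = fit.groups[0], fit.groups[-1]
    n1, n2 = fit.group_sizes[g1], fit.group_sizes[g2]
    csum = (1.0 / n1 + 1.0 / n2) / b
    var, df = _satterthwaite(
        [
            (csum, fit.ms_subject, fit.df_subject),
            (csum * (b - 1), fit.ms_resid, fit.df_resid),
        ]
    )
    se_b = math.sqrt(var)
    for m in fit.measures:
        est = fit.cell_means.loc[g1, m] - fit.cell_means.loc[g2, m]
        t = est / se_b if se_b > 0 else math.nan
        between_rows.append(
            {
                "measure": m, "contrast": f"{g1} - {g2}", "estimate": est,
                "se": se_b, "t": t, "df": df,
                "p": float(2 * sps.t.sf(abs(t), df)) if se_b > 0 else math.nan,
            }
        )
    for g in fit.groups:
        n = fit.group_sizes[g]
        cvar, cdf = _satterthwaite(
            [
                (1.0 / (n * b), fit.ms_subject, fit.df_subject),
                ((b - 1) / (n * b), fit.ms_resid, fit.df_resid),
            ]
        )
        half = sps.t.ppf(1 - alpha / (2 * k_cells), cdf) * math.sqrt(cvar)
        for m in fit.measures:
            mu = fit.cell_means.loc[g, m]
            ci_rows.append(
                {
                    "group": g, "measure": m, "mean": mu,
                    "ci_low": mu - half, "ci_high": mu + half, "df": cdf,
                }
            )
    return {
        "within": pd.DataFrame(within_rows),
        "between": pd.DataFrame(between_rows),
        "cell_means": pd.DataFrame(ci_rows),
    }
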