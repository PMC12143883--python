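"""Statistical tests with SPSS-style reporting conventions.

Covers the repertoire used for the figure statistics: paired/unpaired t
tests (pooled variance, df = n1+n2−2), one-way repeated-measures ANOVA
with the Greenhouse–Geisser (GG) sphericity correction, mixed
(between × within) ANOVA with GG on the within terms, two-way
between-subjects ANOVA with Type III sums of squares, Sidak-adjusted
post-hocs, Kruskal–Wallis with Dunn's post-hoc, and the
normality/homoscedasticity assumption checks (one-sample
Kolmogorov–Smirnov, Brown–Forsythe/median Levene).

Conventions: GG-corrected degrees of freedom are always reported (shown
as ε·df even when ε = 1, e.g. "F (2.000, 12.00)"); all tests are
two-tailed; the t sign convention is first argument minus second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PosthocComparison",
    "paired_t",
    "unpaired_t",
    "rm_anova_gg",
    "mixed_anova",
    "two_way_anova",
    "sidak_adjust",
    "sidak_posthoc",
    "kruskal_wallis",
    "dunn_posthoc",
    "assumption_checks",
    "gg_epsilon",
]


@dataclass
class PosthocComparison:
    contrast: str
    p_raw: float
    p_adj: float
    method: str = "sidak"


@dataclass
class StatResult:
    test: str
    statistic: float
    df1: float
    df2: float | None = None
    epsilon: float = 1.0
    p: float = float("nan")
    term: str = ""
    posthoc: list[PosthocComparison] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __str__(self) -> str:  # printed like the field reports statistics
        if self.df2 is None:
            return f"{self.test}: stat({self.df1:g}) = {self.statistic:.4g}, p = {self.p:.4g}"
        return (
            f"{self.test}{(' [' + self.term + ']') if self.term else ''}: "
            f"F ({self.df1:.3f}, {self.df2:.2f}) = {self.statistic:.4g}, p = {self.p:.4g}"
        )


# ---------------------------------------------------------------------------
# t tests


def _t_result(name: str, t: float, df: float) -> StatResult:
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(test=name, statistic=t, df1=df, p=p)


def paired_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-tailed paired t test; statistic sign is mean(x − y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired t requires equal-length samples with n >= 2")
    d = x - y
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return StatResult(test="paired t", statistic=0.0, df1=df, p=1.0)
        raise ValueError("zero variance with non-zero difference")
    t = d.mean() / (sd / np.sqrt(d.size))
    return _t_result("paired t", float(t), df)


def unpaired_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-tailed unpaired t with pooled variance, df = n1 + n2 − 2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("unpaired t requires n >= 2 per group")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return StatResult(test="unpaired t", statistic=0.0, df1=df, p=1.0)
        raise ValueError("zero pooled variance with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return _t_result("unpaired t", float(t), df)


# ---------------------------------------------------------------------------
# repeated measures


def gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from an (n_subjects × k) score matrix.

    Computed from the double-centered sample covariance of the level
    scores; clipped to [1/(k−1), 1]. For k = 2 it is exactly 1.
    """
    scores = np.asarray(scores, float)
    n, k = scores.shape
    if k == 2:
        return 1.0
    S = np.cov(scores, rowvar=False)
    return _epsilon_from_cov(S, k)


def _epsilon_from_cov(S: np.ndarray, k: int) -> float:
    row = S.mean(axis=0, keepdims=True)
    col = S.mean(axis=1, keepdims=True)
    Sc = S - row - col + S.mean()
    denom = (k - 1) * np.sum(Sc**2)
    if denom <= 0:
        return 1.0
    eps = np.trace(Sc) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _pivot_within(
    table: pd.DataFrame, subject: str, within: str, dv: str
) -> pd.DataFrame:
    wide = table.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        missing = [
            f"{s}×{l}"
            for s in wide.index
            for l in wide.columns
            if pd.isna(wide.loc[s, l])
        ]
        raise ValueError(f"incomplete within-subject design; missing cells: {missing}")
    return wide


def rm_anova_gg(
    table: pd.DataFrame,
    within: str = "level",
    subject: str = "subject",
    dv: str = "value",
    posthoc: bool = True,
) -> StatResult:
    """One-way repeated-measures ANOVA with GG-corrected dfs.

    The long-format ``table`` must contain one row per subject × level.
    The reported dfs are (ε·(k−1), ε·(k−1)(n−1)); ε is always applied.
    Post-hoc: all pairwise paired t tests, Sidak-adjusted.
    """
    wide = _pivot_within(table, subject, within, dv)
    y = wide.to_numpy()
    n, k = y.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 levels and >= 2 subjects")
    grand = y.mean()
    level_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_factor = n * np.sum((level_means - grand) ** 2)
    resid = y - subj_means[:, None] - level_means[None, :] + grand
    ss_error = np.sum(resid**2)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_factor = ss_factor / df1
    ms_error = ss_error / df2
    if ms_error == 0:
        f = 0.0 if ss_factor == 0 else float("inf")
    else:
        f = ms_factor / ms_error
    eps = gg_epsilon(y)
    p = float(sps.f.sf(f, eps * df1, eps * df2)) if np.isfinite(f) else 0.0
    result = StatResult(
        test="one-way RM ANOVA (GG)",
        statistic=float(f),
        df1=eps * df1,
        df2=eps * df2,
        epsilon=eps,
        p=p if f > 0 else (1.0 if f == 0 else p),
    )
    if posthoc and k > 1:
        pairs = list(combinations(range(k), 2))
        raws = []
        for i, j in pairs:
            raws.append(paired_t(y[:, i], y[:, j]).p)
        adj = sidak_adjust(raws, len(pairs))
        labels = list(wide.columns)
        result.posthoc = [
            PosthocComparison(f"{labels[i]} vs {labels[j]}", raw, a)
            for (i, j), raw, a in zip(pairs, raws, adj)
        ]
    return result


def mixed_anova(
    table: pd.DataFrame,
    between: str = "group",
    within: str = "treatment",
    subject: str = "subject",
    dv: str = "value",
) -> StatResult:
    """Mixed (between × within) ANOVA; GG applied to the within terms.

    Returns the interaction term's :class:`StatResult`; the group and
    within main effects ride along in ``flags``-free extra results via
    the ``extras`` attribute set on the returned object.
    """
    wide = _pivot_within(table, subject, within, dv)
    groups = (
        table[[subject, between]].drop_duplicates().set_index(subject)[between]
    )
    if groups.index.duplicated().any():
        raise ValueError("a subject appears in more than one between-group")
    groups = groups.loc[wide.index]
    y = wide.to_numpy()
    n, k = y.shape
    glabels = list(dict.fromkeys(groups))
    g_count = len(glabels)
    if g_count < 2:
        raise ValueError("need >= 2 between-groups")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    level_means = y.mean(axis=0)
    idx_by_g = {g: np.asarray(groups == g) for g in glabels}
    n_g = {g: int(idx_by_g[g].sum()) for g in glabels}

    ss_group = k * sum(
        n_g[g] * (subj_means[idx_by_g[g]].mean() - grand) ** 2 for g in glabels
    )
    ss_subj = k * sum(
        np.sum((subj_means[idx_by_g[g]] - subj_means[idx_by_g[g]].mean()) ** 2)
        for g in glabels
    )
    ss_time = n * np.sum((level_means - grand) ** 2)
    ss_cells = 0.0
    for g in glabels:
        cell = y[idx_by_g[g]].mean(axis=0)
        gmean = subj_means[idx_by_g[g]].mean()
        ss_cells += n_g[g] * np.sum((cell - gmean - level_means + grand) ** 2)
    ss_inter = ss_cells
    ss_error = 0.0
    for g in glabels:
        yg = y[idx_by_g[g]]
        cell = yg.mean(axis=0)
        sm = yg.mean(axis=1)
        ss_error += np.sum((yg - sm[:, None] - cell[None, :] + sm.mean()) ** 2)

    df_group, df_subj = g_count - 1, n - g_count
    df_time = k - 1
    df_inter = (g_count - 1) * (k - 1)
    df_error = (n - g_count) * (k - 1)

    # pooled within-group covariance drives the GG correction
    pooled = np.zeros((k, k))
    for g in glabels:
        yg = y[idx_by_g[g]]
        if yg.shape[0] > 1:
            pooled += (yg.shape[0] - 1) * np.cov(yg, rowvar=False)
    eps = _epsilon_from_cov(pooled / max(n - g_count, 1), k) if k > 2 else 1.0

    scale = max(float(np.sum((y - grand) ** 2)), 1.0)

    def fstat(ss_num, df_num, ss_den, df_den, apply_gg):
        ms_num = ss_num / df_num
        ms_den = ss_den / df_den
        if ms_den <= 1e-12 * scale:
            f = 0.0 if ms_num <= 1e-12 * scale else float("inf")
        else:
            f = ms_num / ms_den
        e = eps if apply_gg else 1.0
        p = 1.0 if f == 0 else float(sps.f.sf(f, e * df_num, e * df_den))
        return float(f), e * df_num, e * df_den, e, p

    f_i, d1_i, d2_i, e_i, p_i = fstat(ss_inter, df_inter, ss_error, df_error, True)
    f_g, d1_g, d2_g, _, p_g = fstat(ss_group, df_group, ss_subj, df_subj, False)
    f_t, d1_t, d2_t, e_t, p_t = fstat(ss_time, df_time, ss_error, df_error, True)

    result = StatResult(
        test="mixed ANOVA (GG)",
        term="interaction",
        statistic=f_i,
        df1=d1_i,
        df2=d2_i,
        epsilon=e_i,
        p=p_i,
    )
    result.extras = {
        "group": StatResult(
            test="mixed ANOVA", term=between, statistic=f_g, df1=d1_g, df2=d2_g, p=p_g
        ),
        "within": StatResult(
            test="mixed ANOVA (GG)",
            term=within,
            statistic=f_t,
            df1=d1_t,
            df2=d2_t,
            epsilon=e_t,
            p=p_t,
        ),
    }
    return result


def two_way_anova(
    table: pd.DataFrame,
    f1: str,
    f2: str,
    dv: str = "value",
) -> dict[str, StatResult]:
    """Two-way between-subjects ANOVA, Type III sums of squares.

    Returns results keyed ``f1``, ``f2`` and ``"interaction"``. Empty
    cells raise (Type III is undefined there).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = table.groupby([f1, f2], observed=True)[dv].count().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        raise ValueError("empty design cells; Type III ANOVA undefined")
    data = table.rename(columns={dv: "_dv", f1: "_f1", f2: "_f2"})
    model = smf.ols("_dv ~ C(_f1, Sum) * C(_f2, Sum)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    rows = {
        f1: "C(_f1, Sum)",
        f2: "C(_f2, Sum)",
        "interaction": "C(_f1, Sum):C(_f2, Sum)",
    }
    df_resid = float(aov.loc["Residual", "df"])
    out = {}
    for key, row in rows.items():
        out[key] = StatResult(
            test="two-way ANOVA (III)",
            term=key,
            statistic=float(aov.loc[row, "F"]),
            df1=float(aov.loc[row, "df"]),
            df2=df_resid,
            p=float(aov.loc[row, "PR(>F)"]),
        )
    return out


# ---------------------------------------------------------------------------
# multiple comparisons


def sidak_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Sidak family-wise adjustment p_adj = 1 − (1 − p)^m, clipped to [0, 1]."""
    p = np.asarray(p_values, float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


def sidak_posthoc(
    contrasts: Sequence[str], p_values: Sequence[float], m: int | None = None
) -> list[PosthocComparison]:
    adj = sidak_adjust(p_values, m)
    return [
        PosthocComparison(c, float(p), float(a))
        for c, p, a in zip(contrasts, p_values, adj)
    ]


# ---------------------------------------------------------------------------
# nonparametric


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    posthoc: bool = True,
) -> StatResult:
    """Tie-corrected Kruskal–Wallis H with Dunn/Sidak post-hoc."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 value each")
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        result = StatResult(
            test="Kruskal-Wallis", statistic=0.0, df1=len(groups) - 1, p=1.0
        )
        return result
    h, p = sps.kruskal(*arrays)
    result = StatResult(
        test="Kruskal-Wallis", statistic=float(h), df1=len(groups) - 1, p=float(p)
    )
    if posthoc:
        if labels is None:
            labels = [f"group{i}" for i in range(len(groups))]
        result.posthoc = dunn_posthoc(arrays, labels)
    return result


def dunn_posthoc(
    groups: Sequence[np.ndarray], labels: Sequence[str]
) -> list[PosthocComparison]:
    """Dunn's rank-based pairwise z tests with Sidak adjustment."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(combinations(range(len(groups)), 2))
    raws, names = [], []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raws.append(2.0 * sps.norm.sf(abs(z)))
        names.append(f"{labels[i]} vs {labels[j]}")
    return sidak_posthoc(names, raws, len(pairs))


# ---------------------------------------------------------------------------
# assumptions


def assumption_checks(
    groups: Sequence[Sequence[float]],
) -> dict[str, float | bool]:
    """Normality (one-sample KS vs fitted normal, pooled residuals) and
    homogeneity of variance (Levene with median centering).

    Returns ``{"ks_p": ..., "levene_p": ..., "degenerate": ...}``; a
    constant sample makes the checks degenerate and is flagged instead of
    producing spurious p values.
    """
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate([a - a.mean() for a in arrays])
    if pooled.size < 3:
        raise ValueError("need at least 3 values overall")
    sd = pooled.std(ddof=1)
    if sd == 0:
        return {"ks_p": float("nan"), "levene_p": float("nan"), "degenerate": True}
    ks = sps.kstest(pooled, "norm", args=(pooled.mean(), sd))
    if len(arrays) >= 2 and all(a.size >= 2 for a in arrays):
        lev = sps.levene(*arrays, center="median")
        lev_p = float(lev.pvalue)
    else:
        lev_p = float("nan")
    return {"ks_p": float(ks.pvalue), "levene_p": lev_p, "degenerate": False}
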