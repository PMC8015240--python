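"""Cohort-level statistics on patient CIs and clinical covariates.

Wraps the standard tests the analysis uses — Shapiro–Wilk normality,
one-way ANOVA with Tukey HSD post hoc (gated on a significant ANOVA),
Welch two-sample t, Kruskal–Wallis, Pearson chi-square on categoricals,
and a pairwise Pearson correlation matrix with Holm-adjusted p-values —
behind a uniform result type, and assembles the full stats report table.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "CorrelationMatrix",
    "shapiro_wilk",
    "one_way_anova",
    "tukey_hsd",
    "welch_t",
    "kruskal_wallis",
    "chi_square_categorical",
    "pearson_correlations",
    "anova_tukey_pipeline",
    "holm_adjust",
    "run_cohort_stats",
]


@dataclass
class GroupComparison:
    """Uniform result of one statistical test."""

    test_name: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    pairwise: list[tuple[str, str, float]] | None = None  # (A, B, adjusted p)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with Holm-adjusted p-values."""

    variables: list[str]
    r: pd.DataFrame
    p_adjusted: pd.DataFrame
    n: pd.DataFrame


def shapiro_wilk(values) -> GroupComparison:
    """Shapiro–Wilk normality test (null: data are normal). Requires n >= 3."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro–Wilk needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values identical")
    w, p = sps.shapiro(x)
    return GroupComparison("shapiro_wilk", float(w), float(p))


def one_way_anova(ci_by_group: dict[str, list[float]]) -> GroupComparison:
    """One-way fixed-effects ANOVA across >= 2 groups, each with n >= 2."""
    if len(ci_by_group) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    arrays = []
    for g, v in ci_by_group.items():
        a = np.asarray(v, dtype=float)
        if a.size < 2:
            raise ValueError(f"group {g!r} has n < 2")
        arrays.append(a)
    f, p = sps.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    if not np.isfinite(f):  # all groups constant and equal
        f, p = 0.0, 1.0
    return GroupComparison("one_way_anova", float(f), float(p), df=(df1, df2))


def tukey_hsd(ci_by_group: dict[str, list[float]]) -> list[tuple[str, str, float]]:
    """All pairwise group comparisons with studentized-range adjusted p-values."""
    if len(ci_by_group) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups")
    names = list(ci_by_group)
    res = sps.tukey_hsd(*(np.asarray(ci_by_group[g], dtype=float) for g in names))
    out = []
    for i, j in itertools.combinations(range(len(names)), 2):
        out.append((names[i], names[j], float(res.pvalue[i, j])))
    return out


def anova_tukey_pipeline(
    ci_by_group: dict[str, list[float]], alpha: float = 0.05
) -> GroupComparison:
    """Gated post-hoc policy: Tukey HSD runs only after a significant ANOVA."""
    res = one_way_anova(ci_by_group)
    if res.p_value < alpha:
        res.pairwise = tukey_hsd(ci_by_group)
    return res


def welch_t(group_a, group_b) -> GroupComparison:
    """Welch two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch t needs n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both groups constant: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    # Welch–Satterthwaite df
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return GroupComparison("welch_t", float(t), float(p), df=float(df))


def kruskal_wallis(values_by_group: dict[str, list[float]]) -> GroupComparison:
    """Kruskal–Wallis rank-sum test with tie correction."""
    if len(values_by_group) < 2:
        raise ValueError("Kruskal–Wallis needs >= 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all values tied across all groups")
    h, p = sps.kruskal(*arrays)
    return GroupComparison("kruskal_wallis", float(h), float(p),
                           df=len(arrays) - 1)


def chi_square_categorical(counts) -> GroupComparison:
    """Pearson chi-square on a 2-way contingency table (no continuity correction)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return GroupComparison("pearson_chi_square", float(chi2), float(p), df=dof)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def pearson_correlations(features: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with Holm-adjusted p-values.

    Columns with fewer than 3 pairwise-complete cases or zero variance get
    NaN entries (flagged via log).  The adjustment family is the set of
    off-diagonal pairs.
    """
    cols = list(features.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    praw = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    pairs = list(itertools.combinations(range(k), 2))
    raw_list, pair_idx = [], []
    for i, j in pairs:
        x = features[cols[i]].astype(float)
        y = features[cols[j]].astype(float)
        ok = x.notna() & y.notna()
        m = int(ok.sum())
        n.iloc[i, j] = n.iloc[j, i] = m
        if m < 3:
            logger.warning("pair (%s, %s): only %d complete cases", cols[i], cols[j], m)
            r.iloc[i, j] = r.iloc[j, i] = np.nan
            continue
        xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            logger.warning("pair (%s, %s): zero variance, correlation undefined",
                           cols[i], cols[j])
            r.iloc[i, j] = r.iloc[j, i] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rv, pv = sps.pearsonr(xv, yv)
        r.iloc[i, j] = r.iloc[j, i] = float(rv)
        raw_list.append(float(pv))
        pair_idx.append((i, j))
    if raw_list:
        adj = holm_adjust(raw_list)
        for (i, j), pa in zip(pair_idx, adj):
            praw.iloc[i, j] = praw.iloc[j, i] = float(pa)
    np.fill_diagonal(praw.values, 0.0)
    for i in range(k):
        n.iloc[i, i] = int(features[cols[i]].notna().sum())
    return CorrelationMatrix(variables=cols, r=r, p_adjusted=praw, n=n)


def run_cohort_stats(
    patient_ci: pd.DataFrame,
    patients: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full cohort statistical stage; returns a tidy stats-report table.

    Stages: per-group Shapiro–Wilk on mean CI (warn-only normality gate),
    ANOVA + gated Tukey on CI by group, Kruskal–Wallis on PSA and prostate
    size, ANOVA on age and BMI, chi-square on smoking by group, Welch t on
    CI by smoking status and (within cancer) by Gleason category, and the
    CI-vs-covariate Pearson correlation matrix.
    """
    df = patient_ci.merge(patients, on=["patient_id", "group"], how="inner")
    rows: list[dict] = []

    def add(test, target, res: GroupComparison, note=""):
        rows.append({
            "test": test, "target": target, "statistic": res.statistic,
            "df": str(res.df) if res.df is not None else "",
            "p_value": res.p_value, "note": note,
        })

    ci_by_group = {g: sub["mean_ci"].tolist() for g, sub in df.groupby("group")}
    for g, vals in ci_by_group.items():
        try:
            sw = shapiro_wilk(vals)
            note = "" if sw.p_value >= alpha else "normality questionable"
            if note:
                logger.warning("group %s fails Shapiro–Wilk (p=%.3g); ANOVA still run",
                               g, sw.p_value)
            add("shapiro_wilk", f"mean_ci[{g}]", sw, note)
        except ValueError as e:
            logger.warning("Shapiro–Wilk skipped for %s: %s", g, e)

    res = anova_tukey_pipeline(ci_by_group, alpha=alpha)
    add("one_way_anova", "mean_ci~group", res)
    if res.pairwise:
        for a, b, p in res.pairwise:
            rows.append({"test": "tukey_hsd", "target": f"mean_ci:{a}-vs-{b}",
                         "statistic": np.nan, "df": "", "p_value": p, "note": ""})

    for col, label in [("psa_ng_ml", "psa"), ("prostate_cm3", "prostate_size")]:
        by_g = {g: sub[col].dropna().tolist() for g, sub in df.groupby("group")}
        by_g = {g: v for g, v in by_g.items() if len(v) >= 2}
        if len(by_g) >= 2:
            add("kruskal_wallis", f"{label}~group", kruskal_wallis(by_g))
    for col, label in [("age_years", "age"), ("bmi", "bmi")]:
        by_g = {g: sub[col].dropna().tolist() for g, sub in df.groupby("group")}
        by_g = {g: v for g, v in by_g.items() if len(v) >= 2}
        if len(by_g) >= 2:
            add("one_way_anova", f"{label}~group", one_way_anova(by_g))

    smoke = pd.crosstab(df["group"], df["smoker"])
    if smoke.shape[1] >= 2 and (smoke.to_numpy().sum(axis=0) > 0).all():
        add("pearson_chi_square", "smoker~group", chi_square_categorical(smoke))

    smokers = df.loc[df["smoker"].astype(bool), "mean_ci"]
    nonsmokers = df.loc[~df["smoker"].astype(bool), "mean_ci"]
    if len(smokers) >= 2 and len(nonsmokers) >= 2:
        add("welch_t", "mean_ci:smoker-vs-nonsmoker", welch_t(smokers, nonsmokers))
    cancer = df[df["group"] == "cancer"]
    low = cancer.loc[cancer["gleason_cat"] == "low", "mean_ci"]
    high = cancer.loc[cancer["gleason_cat"] == "high", "mean_ci"]
    if len(low) >= 2 and len(high) >= 2:
        add("welch_t", "mean_ci:gleason-low-vs-high", welch_t(low, high))

    corr_cols = ["mean_ci", "prostate_cm3", "bmi", "psa_ng_ml", "age_years"]
    corr = pearson_correlations(df[corr_cols])
    for i, a in enumerate(corr.variables):
        for j, b in enumerate(corr.variables):
            if j <= i:
                continue
            rows.append({
                "test": "pearson_r", "target": f"{a}-vs-{b}",
                "statistic": corr.r.iloc[i, j], "df": "",
                "p_value": corr.p_adjusted.iloc[i, j], "note": "holm-adjusted",
            })
    return pd.DataFrame(rows)
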