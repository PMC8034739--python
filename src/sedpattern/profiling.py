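"""Cluster profiling statistics.

Continuous variables are compared across clusters with classical one-way
ANOVA plus pooled-variance Bonferroni pairwise tests; categorical
variables with Pearson chi-square tests plus adjusted standardized
residuals (|r| > 1.96 flags the cells driving a result).  The module
also assembles the three publication-style summary tables: participant
characteristics, device-measured behavior by day type, and
domain-specific self-reported sedentary time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "ChiSquareResult",
    "ProfileTables",
    "anova_oneway",
    "anova_from_summary",
    "chi_square_test",
    "build_profile_tables",
    "format_p",
]

logger = logging.getLogger(__name__)

RESIDUAL_FLAG = 1.96


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    group_ns: dict
    pairwise: dict  # (i, j) -> Bonferroni-adjusted two-sided p

    def significant_pairs(self, alpha: float = 0.05) -> list[str]:
        """Pairs like '1>4' (cluster ids as given), adjusted p < alpha."""
        out = []
        for (i, j), p in self.pairwise.items():
            if p < alpha:
                a, b = (i, j) if self.group_means[i] > self.group_means[j] else (j, i)
                out.append(f"{a}>{b}")
        return out


def _anova_from_sums(means, sds, ns) -> tuple[float, int, int, float]:
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    k = len(means)
    N = int(ns.sum())
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, N - k
    if ssw == 0:
        F = 0.0 if ssb == 0 else np.inf
    else:
        F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return F, df_b, df_w, p


def _bonferroni_pairs(means, sds, ns, df_w, msw, keys) -> dict:
    k = len(keys)
    n_pairs = k * (k - 1) // 2
    out = {}
    for a in range(k):
        for b in range(a + 1, k):
            se = np.sqrt(msw * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                p = 1.0 if means[a] == means[b] else 0.0
            else:
                t = (means[a] - means[b]) / se
                p = min(1.0, 2.0 * float(sps.t.sf(abs(t), df_w)) * n_pairs)
            out[(keys[a], keys[b])] = p
    return out


def anova_oneway(values, groups) -> AnovaResult:
    """Classical one-way ANOVA with pooled-MSW Bonferroni post hoc tests.

    *values* and *groups* are aligned sequences; every group needs at
    least two observations.  Pairwise two-sided t tests share the pooled
    within-group mean square with N-k degrees of freedom; raw p-values
    are multiplied by the number of pairs and capped at 1.
    """
    df = pd.DataFrame({"y": np.asarray(values, float), "g": np.asarray(groups)})
    df = df.dropna()
    keys = sorted(df["g"].unique().tolist())
    if len(keys) < 2:
        raise ValueError("need at least two groups")
    ns, means, sds = [], [], []
    for g in keys:
        y = df.loc[df["g"] == g, "y"].to_numpy()
        if len(y) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        ns.append(len(y))
        means.append(y.mean())
        sds.append(y.std(ddof=1))
    F, df_b, df_w, p = _anova_from_sums(means, sds, ns)
    msw = float(((np.asarray(ns) - 1) * np.asarray(sds) ** 2).sum() / df_w)
    pairwise = _bonferroni_pairs(means, sds, ns, df_w, msw, keys)
    return AnovaResult(
        F=F, df_between=df_b, df_within=df_w, p=p,
        group_means=dict(zip(keys, means)), group_ns=dict(zip(keys, ns)),
        pairwise=pairwise,
    )


def anova_from_summary(means, sds, ns) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group means, SDs and sizes.

    Gives exactly the F any raw data with these summaries would give:
    the between-group sum of squares comes from the means and sizes, the
    within-group sum of squares from (n-1)s^2.
    """
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    if np.any(sds <= 0):
        raise ValueError("all group SDs must be positive")
    if np.any(ns < 2):
        raise ValueError("all group sizes must be >= 2")
    keys = list(range(len(ns)))
    F, df_b, df_w, p = _anova_from_sums(means, sds, ns)
    msw = float(((ns - 1) * sds**2).sum() / df_w)
    pairwise = _bonferroni_pairs(np.asarray(means, float), sds, ns, df_w, msw, keys)
    return AnovaResult(
        F=F, df_between=df_b, df_within=df_w, p=p,
        group_means=dict(zip(keys, np.asarray(means, float))),
        group_ns=dict(zip(keys, ns)), pairwise=pairwise,
    )


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    adjusted_residuals: np.ndarray
    flags: np.ndarray  # |adjusted residual| > 1.96


def chi_square_test(table) -> ChiSquareResult:
    """Pearson chi-square test with adjusted standardized residuals.

    *table* is a categories x clusters count matrix (no continuity
    correction, matching standard contingency-table practice for tables
    larger than 2x2).  The adjusted residual of a cell is
    ``(O - E) / sqrt(E (1 - row_total/N) (1 - col_total/N))``.
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if O.min() < 0 or not np.allclose(O, np.round(O)):
        raise ValueError("table must hold non-negative integer counts")
    N = O.sum()
    if N <= 0:
        raise ValueError("table total must be positive")
    r = O.sum(axis=1, keepdims=True)
    c = O.sum(axis=0, keepdims=True)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("zero row or column margin")
    E = r * c / N
    chi2 = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = (O - E) / np.sqrt(E * (1 - r / N) * (1 - c / N))
    return ChiSquareResult(
        chi2=chi2, df=df, p=p, observed=O, expected=E,
        adjusted_residuals=adj, flags=np.abs(adj) > RESIDUAL_FLAG,
    )


def format_p(p: float) -> str:
    """Three-decimal p-value; below 0.0005 prints '<0.001'."""
    return "<0.001" if p < 0.0005 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# publication-style tables
# ---------------------------------------------------------------------------


@dataclass
class ProfileTables:
    """The three cluster-profile tables plus a machine-readable bundle."""

    characteristics: pd.DataFrame
    behavior: pd.DataFrame
    domains: pd.DataFrame
    results: dict = field(default_factory=dict)


def _cluster_ids(assignments: pd.Series) -> list:
    return sorted(assignments.unique().tolist())


def _characteristics_table(assignments, covariates, clusters, results) -> pd.DataFrame:
    rows = []
    joined = covariates.join(assignments.rename("cluster"), how="inner")
    for var in covariates.columns:
        col = joined[[var, "cluster"]].dropna()
        if pd.api.types.is_numeric_dtype(col[var]):
            try:
                res = anova_oneway(col[var], col["cluster"]) if len(clusters) > 1 else None
            except ValueError:
                res = None
            row = {"variable": var, "category": "(mean, SD)"}
            for k in clusters:
                y = col.loc[col["cluster"] == k, var]
                row[f"cluster_{k}"] = f"{y.mean():.1f} ({y.std(ddof=1):.1f})"
            row["p"] = format_p(res.p) if res else ""
            rows.append(row)
            if res:
                results[f"anova::{var}"] = {"F": res.F, "p": res.p}
            continue
        cats = sorted(col[var].unique().tolist())
        if len(cats) < 2 or len(clusters) < 2:
            logger.info("chi-square skipped for %r (single level)", var)
            ct = None
        else:
            table = np.array(
                [[int(((col[var] == c) & (col["cluster"] == k)).sum()) for k in clusters]
                 for c in cats]
            )
            ct = chi_square_test(table)
            results[f"chi2::{var}"] = {"chi2": ct.chi2, "df": ct.df, "p": ct.p}
        for ci, cat in enumerate(cats):
            row = {"variable": var, "category": cat}
            for kj, k in enumerate(clusters):
                n = int(((col[var] == cat) & (col["cluster"] == k)).sum())
                denom = int((col["cluster"] == k).sum())
                pct = 100.0 * n / denom if denom else np.nan
                flag = "*" if ct is not None and ct.flags[ci, kj] else ""
                row[f"cluster_{k}"] = f"{n} ({pct:.1f}%){flag}"
            row["p"] = format_p(ct.p) if ct is not None and ci == 0 else ""
            rows.append(row)
    return pd.DataFrame(rows)


def _metric_table(assignments, data, variables, clusters, results, label) -> pd.DataFrame:
    """ANOVA rows (mean/SD per cluster + p + significant pairs) for each
    variable; listwise n per variable."""
    rows = []
    for var in variables:
        if var not in data.columns:
            continue
        col = data[[var]].join(assignments.rename("cluster"), how="inner").dropna()
        row = {"variable": var, "n": len(col)}
        res = None
        if len(clusters) > 1:
            try:
                res = anova_oneway(col[var], col["cluster"])
            except ValueError as exc:
                logger.info("ANOVA skipped for %r: %s", var, exc)
        for k in clusters:
            y = col.loc[col["cluster"] == k, var]
            row[f"cluster_{k}"] = (
                f"{y.mean():.1f} ({y.std(ddof=1):.1f})" if len(y) > 1 else ""
            )
        row["p"] = format_p(res.p) if res else ""
        row["post_hoc"] = ",".join(res.significant_pairs()) if res else ""
        rows.append(row)
        if res:
            results[f"{label}::{var}"] = {
                "F": res.F, "p": res.p, "pairs": res.significant_pairs(),
            }
    return pd.DataFrame(rows)


def build_profile_tables(
    assignments: pd.Series,
    covariates: pd.DataFrame | None = None,
    daytype_summaries: pd.DataFrame | None = None,
    domain_sb: pd.DataFrame | None = None,
) -> ProfileTables:
    """Assemble the three cluster-profile tables.

    *assignments* maps participant_id -> cluster id.  *covariates* holds
    sociodemographics (categorical or numeric columns);
    *daytype_summaries* is the output of
    :func:`~sedpattern.features.daytype_summary_table`; *domain_sb*
    holds self-reported domain minutes (columns like ``workday_tv``),
    with per-variable listwise handling of missing values.
    """
    clusters = _cluster_ids(assignments)
    results: dict = {}
    if len(clusters) < 2:
        logger.info("single cluster: test columns omitted")

    characteristics = (
        _characteristics_table(assignments, covariates.set_index(covariates.index), clusters, results)
        if covariates is not None and not covariates.empty
        else pd.DataFrame()
    )

    behavior = pd.DataFrame()
    if daytype_summaries is not None and not daytype_summaries.empty:
        frames = []
        for dt in ("workday", "non_workday", "overall"):
            sub = daytype_summaries[daytype_summaries["day_type"] == dt]
            if sub.empty:
                continue
            wide = sub.set_index("participant_id")
            metrics = [
                "wear_min_whole", "sb_min_whole", "sb_pct_whole",
                "breaks_per_sed_hour_whole", "lipa_pct_whole", "mvpa_pct_whole",
            ]
            tab = _metric_table(
                assignments, wide, metrics, clusters, results, f"behavior::{dt}"
            )
            tab.insert(0, "day_type", dt)
            frames.append(tab)
        if frames:
            behavior = pd.concat(frames, ignore_index=True)

    domains = (
        _metric_table(
            assignments, domain_sb, list(domain_sb.columns), clusters, results, "domain"
        )
        if domain_sb is not None and not domain_sb.empty
        else pd.DataFrame()
    )
    return ProfileTables(
        characteristics=characteristics, behavior=behavior, domains=domains,
        results=results,
    )
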