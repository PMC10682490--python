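"""Covariate-adjusted group inference on network metrics.

The central test is the ANCOVA reading of a covariate-adjusted group
comparison: ordinary least squares of a metric on group indicators plus
covariates (age, sex, education, study site), with the omnibus group effect
assessed by the partial F test of the full model against the covariates-only
model.  For a 10-network partition the family is 10 WNC + 10 OVO + 45 BNC =
65 metrics per contrast, corrected with Benjamini-Hochberg FDR.

Also here: demographic-table statistics (one-way ANOVA with LSD post hoc for
continuous variables, chi-squared for categorical), covariate-controlled
Pearson correlations between metrics and clinical scores, and Wilcoxon
rank-sum heterogeneity screens over sex and age strata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "metric_group_test",
    "metric_test_table",
    "fdr_adjust",
    "demographic_table",
    "partial_pearson",
    "heterogeneity_screen",
    "age_stratum",
    "covariate_design",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "site")


def covariate_design(
    covariates: pd.DataFrame | None, n: int
) -> tuple[np.ndarray, list[str]]:
    """Expand a covariate table to a numeric design with intercept.

    Non-numeric columns (sex, site) become 0/1 indicators with the first
    level dropped; numeric columns pass through.
    """
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        if len(covariates) != n:
            raise DataError(f"covariates have {len(covariates)} rows, data {n}")
        for c in covariates.columns:
            col = covariates[c]
            if col.isna().any():
                raise DataError(f"covariate {c!r} has missing values")
            if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
                cols.append(col.to_numpy(dtype=float))
                names.append(c)
            else:
                levels = sorted(col.astype(str).unique())
                for lev in levels[1:]:
                    cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                    names.append(f"{c}[{lev}]")
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of columns that cannot be added independently
        bad = []
        kept: list[int] = []
        for k in range(X.shape[1]):
            sub = X[:, kept + [k]]
            if np.linalg.matrix_rank(sub) == len(kept) + 1:
                kept.append(k)
            else:
                bad.append(names[k])
        raise DataError(f"rank-deficient design; collinear columns: {bad}")


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    df_num: float
    df_den: float
    p: float


def metric_group_test(
    values: np.ndarray,
    groups: Sequence[str],
    covariates: pd.DataFrame | None = None,
) -> GroupTestResult:
    """Omnibus covariate-adjusted group test on one metric.

    Fits OLS of the metric on group indicators + covariates and tests the
    group indicators jointly with a partial F against the covariates-only
    model.  With no covariates this reduces exactly to one-way ANOVA.
    """
    y = np.asarray(values, dtype=float)
    g = pd.Series(list(groups), dtype=str)
    if y.shape[0] != len(g):
        raise DataError("values and groups have different lengths")
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise DataError("need at least 2 groups")
    counts = g.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise DataError(f"groups with n < 3: {small}")
    Xr, rnames = covariate_design(covariates, len(y))
    gcols = [(g == lev).to_numpy(dtype=float) for lev in levels[1:]]
    gnames = [f"group[{lev}]" for lev in levels[1:]]
    Xf = np.column_stack([Xr] + gcols)
    _check_rank(Xf, rnames + gnames)
    full = sm.OLS(y, Xf).fit()
    restricted = sm.OLS(y, Xr).fit()
    f, p, df_num = full.compare_f_test(restricted)
    return GroupTestResult(float(f), float(df_num), float(full.df_resid), float(p))


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def metric_test_table(
    metrics: pd.DataFrame,
    groups: Sequence[str],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted group test for every metric column, FDR-corrected.

    ``metrics`` is a subjects x metrics frame (one column per WNC/OVO/BNC
    metric); rows align with ``groups`` and ``covariates``.  The FDR family
    is the full metric set of the table.
    """
    rows = []
    for name in metrics.columns:
        res = metric_group_test(metrics[name].to_numpy(), groups, covariates)
        rows.append({"metric": name, "F": res.statistic, "df_num": res.df_num,
                     "df_den": res.df_den, "p": res.p})
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
    table["covariates"] = ",".join(covariates.columns) if covariates is not None else ""
    return table


def _lsd_matrix(y: np.ndarray, g: pd.Series, levels: list[str]) -> pd.DataFrame:
    """Pairwise LSD p-values: t tests on the pooled ANOVA error term.

    LSD means uncorrected pairwise comparisons; the pooled within-group mean
    square provides the common error variance, df = N - k.
    """
    n = {lev: (g == lev).sum() for lev in levels}
    mean = {lev: y[(g == lev).to_numpy()].mean() for lev in levels}
    sse = sum(((y[(g == lev).to_numpy()] - mean[lev]) ** 2).sum() for lev in levels)
    df = len(y) - len(levels)
    mse = sse / df
    out = pd.DataFrame(np.nan, index=levels, columns=levels)
    for a, b in itertools.combinations(levels, 2):
        se = np.sqrt(mse * (1 / n[a] + 1 / n[b]))
        t = (mean[a] - mean[b]) / se
        p = 2 * sps.t.sf(abs(t), df)
        out.loc[a, b] = out.loc[b, a] = p
    return out


def demographic_table(
    subjects: pd.DataFrame,
    continuous: Sequence[str] = ("age", "education"),
    categorical: Sequence[str] = ("sex",),
    group_col: str = "group",
    yates_2x2: bool = False,
) -> dict:
    """Demographic-table statistics across groups.

    Continuous variables: one-way ANOVA F with an LSD post-hoc p-matrix.
    Categorical variables: chi-squared on the contingency table, without
    Yates continuity correction by default (``yates_2x2`` enables it for
    2x2 tables only).
    """
    g = subjects[group_col].astype(str)
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise DataError("need at least 2 groups")
    rows = []
    lsd: dict[str, pd.DataFrame] = {}
    for var in continuous:
        y = subjects[var].to_numpy(dtype=float)
        samples = [y[(g == lev).to_numpy()] for lev in levels]
        if any(len(s) < 2 for s in samples):
            raise DataError(f"a group has n < 2 for ANOVA on {var!r}")
        f, p = sps.f_oneway(*samples)
        rows.append({"variable": var, "test": "anova", "statistic": float(f),
                     "p": float(p)})
        lsd[var] = _lsd_matrix(y, g, levels)
    for var in categorical:
        table = pd.crosstab(subjects[var], g).to_numpy()
        correction = yates_2x2 and table.shape == (2, 2)
        chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
        rows.append({"variable": var, "test": "chi2", "statistic": float(chi2),
                     "p": float(p)})
    return {"tests": pd.DataFrame(rows), "lsd": lsd}


def partial_pearson(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Pearson correlation of two variables after removing covariates.

    Both variables are residualized on the covariates (with intercept); the
    correlation of the residuals is tested with a t statistic on
    n - n_covariates - 2 degrees of freedom.  With no covariates this is the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    C, names = covariate_design(covariates, n)
    k = C.shape[1] - 1  # expanded covariate count, excluding intercept
    if n <= k + 2:
        raise DataError(f"n={n} too small for {k} covariates")
    _check_rank(C, names)
    beta_x, *_ = np.linalg.lstsq(C, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(C, y, rcond=None)
    rx, ry = x - C @ beta_x, y - C @ beta_y
    # a variable fully explained by the covariates has no residual signal
    for resid, orig in ((rx, x), (ry, y)):
        if (resid ** 2).sum() <= 1e-12 * max((orig ** 2).sum(), 1e-30):
            return 0.0, 1.0
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    r = float((rx * ry).sum() / denom)
    df = n - k - 2
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * np.sqrt(df / (1 - r_ ** 2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def age_stratum(age: np.ndarray, young: tuple[int, int] = (18, 37),
                old: tuple[int, int] = (38, 65)) -> pd.Series:
    """Closed-interval age split: 18-37 younger, 38-65 older, else NaN."""
    a = pd.Series(np.asarray(age, dtype=float))
    out = pd.Series(pd.NA, index=a.index, dtype="object")
    out[(a >= young[0]) & (a <= young[1])] = "younger"
    out[(a >= old[0]) & (a <= old[1])] = "older"
    return out


def _ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p.

    Exact enumeration when both samples have n <= 10 and no ties; otherwise
    the tie-corrected normal approximation.
    """
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) <= 10) and (len(b) <= 10) and not ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def heterogeneity_screen(
    data: pd.DataFrame,
    strata: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum screen of every column across a two-level split.

    ``strata`` holds two labels (e.g. female/male or younger/older); rows
    with missing stratum are dropped.  Returns statistic, p, log10(p) and a
    significance flag at ``alpha`` per variable.  The conventional reference
    line on the log scale is log10(0.05) ~= -1.301.
    """
    s = pd.Series(list(strata), index=data.index)
    keep = s.notna()
    s = s[keep]
    levels = sorted(s.unique())
    if len(levels) != 2:
        raise DataError(f"need exactly 2 strata, got {levels}")
    a_idx, b_idx = (s == levels[0]), (s == levels[1])
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise DataError("each stratum needs at least 2 subjects")
    rows = []
    for col in data.columns:
        v = data.loc[keep, col].to_numpy(dtype=float)
        stat, p = _ranksum(v[a_idx.to_numpy()], v[b_idx.to_numpy()])
        rows.append({
            "variable": col, "stratum_a": levels[0], "stratum_b": levels[1],
            "statistic": stat, "p": p,
            "log10_p": float(np.log10(p)) if p > 0 else -np.inf,
            "significant": p < alpha,
        })
    return pd.DataFrame(rows)
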