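"""Population statistics over cell tables grouped by time point.

Summaries follow box-and-whisker conventions (median, 1st–3rd quartile by
linear interpolation, min/max) with the unbiased sample variance and a
seeded nonparametric bootstrap percentile 95% CI on the variance. Group
comparisons use the two-sided Wilcoxon/Mann–Whitney rank-sum test — exact
enumeration (midranks, tie-aware) when both groups have ≤ 10 observations,
tie-corrected normal approximation otherwise — with Holm adjustment across
all pairs. The intensity-on-length relationship is summarized by ordinary
least squares with the adjusted R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .morphometry import LENGTH_SPLIT_UM, LONG

EXACT_MAX_N = 10  # exact rank-sum enumeration when both groups are this size or smaller

_FEATURE_COLUMNS = {
    "length": "length_um",
    "width": "width_um",
    "mean_intensity": "mean_intensity_au",
}


def _feature_column(records: pd.DataFrame, feature: str) -> str:
    col = _FEATURE_COLUMNS.get(feature, feature)
    if col not in records.columns:
        raise KeyError(f"feature column {col!r} not in records")
    return col


@dataclass(frozen=True)
class PopulationSummary:
    """Distribution summary of one feature within one group."""

    group: object
    n: int
    median: float
    q1: float
    q3: float
    min: float
    max: float
    variance: float
    variance_ci: tuple[float, float]  # 95% bootstrap percentile interval
    long_fraction: float


@dataclass(frozen=True)
class PairwiseTestResult:
    group_a: object
    group_b: object
    statistic: float  # Mann–Whitney U of group_a
    p_raw: float
    p_adjusted: float
    method: str


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # a.u. per µm
    intercept: float  # a.u.
    r_squared_adjusted: float
    n: int
    p_value: float  # slope t-test


def bootstrap_variance_ci(
    x: np.ndarray, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Seeded nonparametric bootstrap percentile CI for the sample variance."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot_var = np.var(x[idx], axis=1, ddof=1)
    a = 100.0 * (1.0 - level) / 2.0
    return (float(np.percentile(boot_var, a)), float(np.percentile(boot_var, 100.0 - a)))


def summarize_population(
    records: pd.DataFrame,
    group_key: str,
    feature: str = "length",
    n_boot: int = 1000,
    seed: int = 0,
) -> list[PopulationSummary]:
    """Per-group distribution summaries with a bootstrap variance CI.

    Groups with fewer than 2 observations are omitted with a warning (the
    sample variance is undefined there). ``long_fraction`` is the fraction
    of cells longer than 4 µm, computed from the length column when present.
    """
    col = _feature_column(records, feature)
    rng = np.random.default_rng(seed)
    out: list[PopulationSummary] = []
    for group, sub in records.groupby(group_key, sort=True):
        x = sub[col].dropna().to_numpy(dtype=float)
        if x.size < 2:
            warnings.warn(f"group {group!r} has fewer than 2 observations; omitted")
            continue
        variance = float(np.var(x, ddof=1))
        ci = bootstrap_variance_ci(x, n_boot=n_boot, seed=int(rng.integers(2**31)))
        if "length_um" in sub.columns:
            lf = float((sub["length_um"] > LENGTH_SPLIT_UM).mean())
        else:
            lf = float("nan")
        out.append(
            PopulationSummary(
                group=group,
                n=int(x.size),
                median=float(np.median(x)),
                q1=float(np.percentile(x, 25)),
                q3=float(np.percentile(x, 75)),
                min=float(x.min()),
                max=float(x.max()),
                variance=variance,
                variance_ci=ci,
                long_fraction=lf,
            )
        )
    return out


def summaries_to_frame(summaries: list[PopulationSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "group": s.group,
                "n": s.n,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "min": s.min,
                "max": s.max,
                "variance": s.variance,
                "variance_ci_low": s.variance_ci[0],
                "variance_ci_high": s.variance_ci[1],
                "long_fraction": s.long_fraction,
            }
        )
    return pd.DataFrame(rows)


def rank_sum_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by full enumeration (midranks, tie-aware).

    Enumerates all C(n, n_a) assignments of the pooled midranks to group a;
    the p-value is the null probability of a rank sum at least as far from
    its expectation as observed. Returns (U statistic of a, p).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, n = a.size, pooled.size
    w_obs = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0
    d_obs = abs(w_obs - mu)
    count = 0
    for idx in combinations(range(n), na):
        if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-9:
            count += 1
    p = count / comb(n, na)
    u = w_obs - na * (na + 1) / 2.0
    return u, p


def pairwise_wilcoxon(
    records: pd.DataFrame,
    group_key: str,
    feature: str = "length",
    adjust: str = "holm",
) -> list[PairwiseTestResult]:
    """Two-sided rank-sum test for every unordered pair of groups.

    Uses exact enumeration when both groups have ≤ 10 observations and the
    tie-corrected normal approximation (with continuity correction)
    otherwise. P-values are adjusted across all pairs (Holm by default).
    Pairs involving a group with < 2 observations are skipped with a
    warning.
    """
    col = _feature_column(records, feature)
    groups = {g: sub[col].dropna().to_numpy(dtype=float) for g, sub in records.groupby(group_key, sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pairs, stats_list, praw, methods = [], [], [], []
    for ga, gb in combinations(sorted(groups, key=str), 2):
        a, b = groups[ga], groups[gb]
        if a.size < 2 or b.size < 2:
            warnings.warn(f"pair ({ga!r}, {gb!r}) skipped: a group has < 2 observations")
            continue
        if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
            u, p = rank_sum_exact_p(a, b)
            method = "exact-enumeration"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
            method = "normal-approximation-tie-corrected"
        pairs.append((ga, gb))
        stats_list.append(u)
        praw.append(p)
        methods.append(method)
    if not pairs:
        return []
    adjusted = multipletests(praw, method=adjust)[1]
    return [
        PairwiseTestResult(
            group_a=ga,
            group_b=gb,
            statistic=u,
            p_raw=float(p),
            p_adjusted=float(pa),
            method=f"wilcoxon-rank-sum/{m}+{adjust}",
        )
        for (ga, gb), u, p, pa, m in zip(pairs, stats_list, praw, adjusted, methods)
    ]


def tests_to_frame(results: list[PairwiseTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.group_a,
                "group_b": r.group_b,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "method": r.method,
            }
            for r in results
        ]
    )


def regress_intensity_on_length(records: pd.DataFrame) -> RegressionResult:
    """OLS of per-cell mean fluorescence intensity on cell length.

    Reports slope (a.u./µm), intercept (a.u.), the adjusted R²
    (1 − (1 − R²)(n − 1)/(n − 2)) and the slope's two-sided t-test p-value.
    """
    sub = records[["length_um", "mean_intensity_au"]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need at least 3 complete observations, got {n}")
    x = sub["length_um"].to_numpy(dtype=float)
    y = sub["mean_intensity_au"].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("zero variance in length; regression undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared_adjusted=float(fit.rsquared_adj),
        n=n,
        p_value=float(fit.pvalues[1]),
    )


def subpopulation_trajectory(summaries: list[PopulationSummary]) -> pd.DataFrame:
    """Short/long subpopulation fractions per group; fractions sum to 1."""
    rows = [
        {
            "group": s.group,
            "long_fraction": s.long_fraction,
            "short_fraction": 1.0 - s.long_fraction,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=["group", "long_fraction", "short_fraction"])
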