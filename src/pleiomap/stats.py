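"""Downstream univariate statistics.

Relative growth rate from paired leaf areas, one-way ANOVA with percent
variance explained, trait–trait genetic correlation on line means, and
Bonferroni-corrected Welch t-tests of climate variables between focal
allele classes with rank summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import AnovaResult, ClimateTable, PleiomapError

__all__ = [
    "growth_rate",
    "one_way_anova",
    "genetic_correlation",
    "climate_tests",
    "rank_summary",
]


def growth_rate(la1, la2, t1: float, t2: float) -> np.ndarray:
    """Relative growth rate of leaf area per day.

    GR_la = (ln LA_t2 - ln LA_t1) / (t2 - t1) for leaf areas measured at
    days t1 < t2.  Scalar or vector areas; nan propagates.
    """
    la1 = np.asarray(la1, dtype=float)
    la2 = np.asarray(la2, dtype=float)
    if t2 <= t1:
        raise PleiomapError(f"t2 must exceed t1 (got {t1}, {t2})")
    if np.any(la1[~np.isnan(la1)] <= 0) or np.any(la2[~np.isnan(la2)] <= 0):
        raise PleiomapError("leaf areas must be positive")
    return (np.log(la2) - np.log(la1)) / (t2 - t1)


def one_way_anova(values, groups) -> AnovaResult:
    """One-way fixed-effect ANOVA with percent variance explained.

    PVE = SSB / SST * 100.  Missing values are dropped pairwise with
    their group labels.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~pd.isna(values) & ~pd.isna(groups)
    values, groups = values[keep], groups[keep]
    levels, idx = np.unique(groups, return_inverse=True)
    if levels.size < 2:
        raise PleiomapError("need >= 2 groups")
    counts = np.bincount(idx)
    if counts.min() == 0:
        raise PleiomapError("empty group")
    n = values.size
    df_b = levels.size - 1
    df_w = n - levels.size
    if df_w < 1:
        raise PleiomapError("need >= 1 residual degree of freedom")
    grand = values.mean()
    means = np.bincount(idx, weights=values) / counts
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((values - means[idx]) ** 2))
    sst = ssb + ssw
    if sst == 0:
        return AnovaResult(F=0.0, df_between=df_b, df_within=df_w,
                           p_value=1.0, pve=0.0)
    if ssw == 0:
        return AnovaResult(F=float("inf"), df_between=df_b, df_within=df_w,
                           p_value=0.0, pve=100.0)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w,
                       p_value=p, pve=ssb / sst * 100.0)


def genetic_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r² between paired line means with its two-sided p.

    Pairwise-complete cases.  Returns (r², p, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise PleiomapError("need >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise PleiomapError("zero variance in one of the vectors")
    r, p = sps.pearsonr(x, y)
    return float(r * r), float(p), n


def climate_tests(climate: ClimateTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable Welch t-tests between focal classes, Bonferroni corrected.

    The family size is the number of climate variables; the adjusted
    p-value is min(1, raw p × n_variables) and the significance flag is
    adjusted p < alpha.  The t statistic is class 1 minus class 0.
    """
    y = np.asarray(climate.labels)
    g1 = y == 1
    g0 = y == 0
    if g1.sum() < 2 or g0.sum() < 2:
        raise PleiomapError("need >= 2 accessions per class")
    m = len(climate.variables)
    rows = []
    for var in climate.variables:
        v = climate.values[var].to_numpy(dtype=float)
        a, b = v[g1], v[g0]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.std() == 0 and b.std() == 0:
            raise PleiomapError(f"variable {var!r} constant within both classes")
        t, p = sps.ttest_ind(a, b, equal_var=False)
        # Welch–Satterthwaite degrees of freedom
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
        p_adj = min(1.0, float(p) * m)
        rows.append({"variable": var, "t": float(t), "df": float(df),
                     "p_raw": float(p), "p_bonferroni": p_adj,
                     "significant": p_adj < alpha})
    return pd.DataFrame(rows).set_index("variable")


def rank_summary(climate: ClimateTable) -> pd.DataFrame:
    """Mean normalized rank of each class per climate variable.

    Values of both classes are pooled and rank-transformed (average ranks
    for ties); each class's mean rank is normalized by (N + 1), so equal
    class distributions sit at 0.5 and complete separation approaches
    0.25 / 0.75 for equal class sizes.
    """
    y = np.asarray(climate.labels)
    rows = []
    for var in climate.variables:
        v = climate.values[var].to_numpy(dtype=float)
        keep = ~np.isnan(v) & ((y == 0) | (y == 1))
        ranks = sps.rankdata(v[keep])
        yk = y[keep]
        N = ranks.size
        rows.append({
            "variable": var,
            "mean_rank_functional": float(ranks[yk == 1].mean() / (N + 1)),
            "mean_rank_null": float(ranks[yk == 0].mean() / (N + 1)),
            "n": N,
        })
    return pd.DataFrame(rows).set_index("variable")
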