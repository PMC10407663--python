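"""Spatial-temporal association layer: annual series, provincial
aggregation, rank correlations against pesticide usage and dosage, and
rank-based group comparisons.

Pesticide *dosage* normalizes a province's annual pesticide usage by its
agricultural production (kg of pesticide per ton of produce), so that large
agricultural provinces are comparable with small ones.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ResidueRecord, UsageRecord, ValidationError
from .summary import DEFAULT_THRESHOLD, summarize

__all__ = ["ProvinceYearMetric", "pesticide_dosage", "rank_correlation",
           "group_difference", "annual_series", "province_table",
           "province_year_metrics", "spatial_association"]

#: Below this sample size the Spearman p-value is computed by exact
#: enumeration of all permutations; above, by the t approximation.
EXACT_PERMUTATION_N = 10


from dataclasses import dataclass


@dataclass(frozen=True)
class ProvinceYearMetric:
    """One (province, year) cell in long format.  ``metric_name`` is one of
    df_ge_threshold (fraction), median_above (mg kg^-1), usage (t) or
    dosage (kg t^-1); dosage exists only where both usage and production
    are reported."""

    province: str
    year: int
    metric_name: str
    value: float


def province_year_metrics(records: Sequence[ResidueRecord],
                          usage_table: Sequence[UsageRecord] = (),
                          threshold: float = DEFAULT_THRESHOLD
                          ) -> list[ProvinceYearMetric]:
    """Long-format provincial annual metrics: residue summaries per
    (province, year) plus usage and, where production is known, dosage."""
    out: list[ProvinceYearMetric] = []
    for s in summarize(records, ["province", "year"], threshold=threshold):
        prov, yr = s.group_key["province"], s.group_key["year"]
        out.append(ProvinceYearMetric(prov, yr, "df_ge_threshold",
                                      s.df_ge_threshold))
        if s.median_above is not None:
            out.append(ProvinceYearMetric(prov, yr, "median_above",
                                          s.median_above))
    for u in usage_table:
        out.append(ProvinceYearMetric(u.province, u.year, "usage",
                                      u.pesticide_usage))
        if u.agricultural_production is not None:
            out.append(ProvinceYearMetric(
                u.province, u.year, "dosage",
                pesticide_dosage(u.pesticide_usage, u.agricultural_production)))
    return out


def pesticide_dosage(usage_tons: float, production_tons: float) -> float:
    """kg of pesticide applied per ton of agricultural produce."""
    if production_tons <= 0:
        raise ValidationError("production must be positive")
    return usage_tons * 1000.0 / production_tons


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    # enumerate all n! permutations of one rank vector; rho is monotone in
    # the rank inner product, so only dot products are needed
    n = len(rx)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    s_obs = abs(rho_obs) * denom
    # vectorized in manageable chunks
    count = 0
    total = 0
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, 200_000))
        if not block:
            break
        perm_ranks = ry[np.asarray(block)]
        s = np.abs(perm_ranks @ rx)
        count += int((s >= s_obs - 1e-9 * max(1.0, s_obs)).sum())
        total += len(block)
    return count / total


def rank_correlation(x: Sequence[float], y: Sequence[float]
                     ) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p-value: exact permutation enumeration for n <= 10 (small
    provincial comparisons need exactness), t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("rank correlation of a constant vector is undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= EXACT_PERMUTATION_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, min(1.0, p)


def group_difference(groups: Sequence[Sequence[float]]
                     ) -> tuple[float, float, str]:
    """Two-sided rank test between groups: Mann-Whitney U for exactly two
    groups, Kruskal-Wallis for three or more.  Tie-corrected statistics."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("groups must be non-empty")
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue), "mann_whitney"
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue), "kruskal_wallis"


def annual_series(records: Sequence[ResidueRecord],
                  usage_table: Sequence[UsageRecord] | None = None,
                  threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-year detection frequency and conditional median, joined with
    national pesticide usage (sum over provinces).  Years without a usage
    datum carry NaN usage — recent usage statistics typically lag the
    survey by a year or more."""
    summaries = summarize(records, ["year"], threshold=threshold)
    rows = [{"year": s.group_key["year"], "n": s.n,
             "df_ge_threshold": s.df_ge_threshold,
             "median_above": np.nan if s.median_above is None else s.median_above}
            for s in summaries]
    out = pd.DataFrame(rows).set_index("year").sort_index()
    usage = pd.Series(np.nan, index=out.index, name="usage_t")
    if usage_table:
        per_year: dict[int, float] = {}
        for u in usage_table:
            per_year[u.year] = per_year.get(u.year, 0.0) + u.pesticide_usage
        for yr, tot in per_year.items():
            if yr in usage.index:
                usage.loc[yr] = tot
    out["usage_t"] = usage
    return out


def province_table(records: Sequence[ResidueRecord],
                   usage_table: Sequence[UsageRecord],
                   threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Province-level aggregates: pooled detection frequency and conditional
    median of the records, mean annual usage, and mean dosage over the
    years where both usage and production are reported."""
    summaries = summarize(records, ["province"], threshold=threshold)
    rows = {s.group_key["province"]:
            {"n": s.n, "df_ge_threshold": s.df_ge_threshold,
             "median_above": np.nan if s.median_above is None else s.median_above}
            for s in summaries}
    usage_by_prov: dict[str, list[float]] = {}
    dosage_by_prov: dict[str, list[float]] = {}
    for u in usage_table:
        usage_by_prov.setdefault(u.province, []).append(u.pesticide_usage)
        if u.agricultural_production is not None:
            dosage_by_prov.setdefault(u.province, []).append(
                pesticide_dosage(u.pesticide_usage, u.agricultural_production))
    for prov, row in rows.items():
        row["mean_usage_t"] = float(np.mean(usage_by_prov[prov])) \
            if prov in usage_by_prov else np.nan
        row["mean_dosage_kg_per_t"] = float(np.mean(dosage_by_prov[prov])) \
            if prov in dosage_by_prov else np.nan
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def spatial_association(records: Sequence[ResidueRecord],
                        usage_table: Sequence[UsageRecord],
                        residue_metric: str = "median_above",
                        usage_metric: str = "mean_usage_t",
                        threshold: float = DEFAULT_THRESHOLD
                        ) -> tuple[float, float, pd.DataFrame]:
    """Spearman association between a provincial residue aggregate
    (``median_above`` or ``df_ge_threshold``) and a provincial usage
    aggregate (``mean_usage_t`` or ``mean_dosage_kg_per_t``), over the
    provinces where both are defined."""
    table = province_table(records, usage_table, threshold)
    sub = table[[residue_metric, usage_metric]].dropna()
    if len(sub) < 3:
        raise ValidationError("fewer than 3 provinces with both metrics")
    rho, p = rank_correlation(sub[usage_metric].to_numpy(),
                              sub[residue_metric].to_numpy())
    return rho, p, table
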