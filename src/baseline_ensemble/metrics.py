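"""Summary statistics over the baseline grid.

* relative variability: CV = 100 x sample SD / mean of a jurisdiction's
  baselines, overall and restricted to each level of each grid parameter;
* hindcast accuracy: forecast error = |predicted - actual| / actual, where
  a method is fitted on a reference window and scored against the observed
  mean rate over the following window of equal duration;
* uncertainty summaries: per-jurisdiction medians of relative uncertainty
  by component (baseline, projection, carbon, AGBC, BGBC) and the fraction
  of methods exceeding a threshold (15% by default, the level above which
  carbon standards typically require a discount);
* level comparisons: one-way ANOVA with Tukey HSD post-hoc tests of
  per-jurisdiction level statistics between the levels of a parameter;
* the correlation between log forest area and overall variability.

Per-jurisdiction statistics use medians across methods; distributions
across jurisdictions are summarised by their median and central 90% range
(5th-95th percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .synthetic_data import JurisdictionPanel

__all__ = [
    "relative_variability",
    "overall_variability",
    "per_level_variability",
    "hindcast_evaluate",
    "hindcast_table",
    "uncertainty_summaries",
    "LevelComparison",
    "compare_levels",
    "area_variability_correlation",
    "median_and_range",
]

GRID_PARAMETERS = [
    "approach",
    "defor_variant",
    "ref_length",
    "start_year",
    "carbon_mask_variant",
    "agb_source",
    "bgb_source",
    "soc_source",
]


def relative_variability(values) -> float:
    """CV as a percentage: 100 x sample SD (n-1 denominator) / mean.

    Undefined (NaN) for fewer than two values or a non-positive mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)


def _valid(baselines: pd.DataFrame) -> pd.DataFrame:
    finite = np.isfinite(baselines["baseline"].to_numpy(dtype=float))
    return baselines[baselines["valid"] & finite]


def overall_variability(baselines: pd.DataFrame) -> pd.DataFrame:
    """Per-jurisdiction CV of valid baselines across all methods."""
    rows = []
    for jid, g in _valid(baselines).groupby("jurisdiction_id", sort=True):
        rows.append(
            {
                "jurisdiction_id": jid,
                "scope": "overall",
                "parameter": "all",
                "level": "all",
                "cv_percent": relative_variability(g["baseline"]),
                "n_methods": len(g),
            }
        )
    return pd.DataFrame(rows)


def per_level_variability(
    baselines: pd.DataFrame, parameter: str
) -> pd.DataFrame:
    """Per-jurisdiction CV restricted to each level of one parameter,
    all other parameters free; subsets with fewer than two valid
    baselines are reported as NaN."""
    rows = []
    for (jid, level), g in _valid(baselines).groupby(
        ["jurisdiction_id", parameter], sort=True, observed=True
    ):
        rows.append(
            {
                "jurisdiction_id": jid,
                "scope": "level",
                "parameter": parameter,
                "level": str(level),
                "cv_percent": relative_variability(g["baseline"]),
                "n_methods": len(g),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hindcasting


def hindcast_evaluate(
    panel: JurisdictionPanel,
    variant: str,
    window: tuple[int, int],
    predicted_rate: float,
    approach: str = "",
) -> dict | None:
    """Score one projection against the window that follows its reference
    window (same duration).  Returns None (skipped) when the following
    window is not covered by the data or the actual mean rate is zero."""
    start, length = window
    series = panel.defor_by_variant.get(variant)
    if series is None:
        return None
    future = np.arange(start + length, start + 2 * length)
    if any(y not in series.index for y in future):
        return None
    actual = float(series.loc[future].mean())
    if actual <= 0 or not np.isfinite(predicted_rate):
        return None
    return {
        "jurisdiction_id": panel.jurisdiction_id,
        "approach": approach,
        "defor_variant": variant,
        "ref_length": length,
        "start_year": start,
        "predicted_rate": predicted_rate,
        "actual_rate": actual,
        "forecast_error": abs(predicted_rate - actual) / actual,
    }


def hindcast_table(
    panels: list[JurisdictionPanel], projections: pd.DataFrame
) -> pd.DataFrame:
    """Forecast errors for every valid projection whose following window
    is available.  Records with zero actual rate are excluded (not
    assigned infinite error); the exclusion count is in ``df.attrs``."""
    by_id = {p.jurisdiction_id: p for p in panels}
    rows, n_zero = [], 0
    valid = projections[projections["valid"] & projections["point_rate"].notna()]
    for row in valid.itertuples(index=False):
        panel = by_id.get(row.jurisdiction_id)
        if panel is None:
            continue
        series = panel.defor_by_variant.get(row.defor_variant)
        if series is None:
            continue
        future = np.arange(
            row.start_year + row.ref_length, row.start_year + 2 * row.ref_length
        )
        if any(y not in series.index for y in future):
            continue
        actual = float(series.loc[future].mean())
        if actual <= 0:
            n_zero += 1
            continue
        rows.append(
            {
                "jurisdiction_id": row.jurisdiction_id,
                "approach": row.approach,
                "defor_variant": row.defor_variant,
                "ref_length": row.ref_length,
                "start_year": row.start_year,
                "predicted_rate": row.point_rate,
                "actual_rate": actual,
                "forecast_error": abs(row.point_rate - actual) / actual,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_excluded_zero_actual"] = n_zero
    return df


# ---------------------------------------------------------------------------
# uncertainty summaries

#: component -> baselines column holding its relative uncertainty
UNCERTAINTY_COMPONENTS = {
    "baseline": "propagated_rel_u",
    "projection": "rate_rel_u",
    "carbon": "carbon_rel_u",
    "agbc": "agb_rel_u",
    "bgbc": "bgb_rel_u",
}


def uncertainty_summaries(
    baselines: pd.DataFrame, threshold_pct: float = 15.0
) -> pd.DataFrame:
    """Per-jurisdiction median relative uncertainty (%) and fraction of
    methods above the threshold, for each uncertainty component.

    ``hist`` combinations carry no model uncertainty and drop out of the
    baseline/projection pools automatically (their uncertainties are NaN).
    """
    rows = []
    for jid, g in _valid(baselines).groupby("jurisdiction_id", sort=True):
        for component, col in UNCERTAINTY_COMPONENTS.items():
            u = g[col].to_numpy(dtype=float)
            u = u[np.isfinite(u)] * 100.0
            if u.size == 0:
                rows.append(
                    {
                        "jurisdiction_id": jid,
                        "component": component,
                        "median_rel_uncertainty_pct": float("nan"),
                        "fraction_exceeding_threshold": float("nan"),
                        "threshold_pct": threshold_pct,
                        "n_methods": 0,
                    }
                )
                continue
            rows.append(
                {
                    "jurisdiction_id": jid,
                    "component": component,
                    "median_rel_uncertainty_pct": float(np.median(u)),
                    "fraction_exceeding_threshold": float(np.mean(u > threshold_pct)),
                    "threshold_pct": threshold_pct,
                    "n_methods": int(u.size),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# level comparisons (ANOVA + Tukey HSD)


@dataclass
class LevelComparison:
    parameter: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame  # level_1, level_2, mean_diff, p_adj, reject
    levels: tuple[str, ...]
    dropped_levels: tuple[str, ...] = ()


def compare_levels(level_values: pd.DataFrame, parameter: str) -> LevelComparison:
    """One-way ANOVA + Tukey HSD across the levels of one parameter.

    ``level_values`` has one row per (jurisdiction, level) with a ``value``
    column (e.g. that jurisdiction's CV using only that level);
    jurisdiction-level values are treated as independent observations
    within each level.  Levels with fewer than two finite values are
    dropped with a warning entry.
    """
    df = level_values[["level", "value"]].dropna()
    groups, dropped = {}, []
    for level, g in df.groupby("level", sort=True):
        if len(g) >= 2:
            groups[str(level)] = g["value"].to_numpy(dtype=float)
        else:
            dropped.append(str(level))
    if len(groups) < 2:
        raise ValueError(f"{parameter}: need >=2 levels with >=2 values each")
    f, p = scipy.stats.f_oneway(*groups.values())
    n_total = sum(len(v) for v in groups.values())
    data = np.concatenate(list(groups.values()))
    labels = np.concatenate([[lv] * len(v) for lv, v in groups.items()])
    tk = pairwise_tukeyhsd(data, labels, alpha=0.05)
    tukey = pd.DataFrame(
        tk.summary().data[1:],
        columns=[c.replace("-", "_") for c in tk.summary().data[0]],
    ).rename(
        columns={
            "group1": "level_1",
            "group2": "level_2",
            "meandiff": "mean_diff",
            "p_adj": "p_adj",
        }
    )[["level_1", "level_2", "mean_diff", "p_adj", "reject"]]
    return LevelComparison(
        parameter=parameter,
        f_statistic=float(f),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
        p_value=float(p),
        tukey=tukey,
        levels=tuple(groups),
        dropped_levels=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# area-variability correlation


def area_variability_correlation(
    forest_area_km2, cv_percent
) -> tuple[float, float]:
    """Pearson correlation between log forest area and overall CV."""
    a = np.asarray(forest_area_km2, dtype=float)
    c = np.asarray(cv_percent, dtype=float)
    mask = np.isfinite(a) & np.isfinite(c) & (a > 0)
    a, c = a[mask], c[mask]
    if a.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(c) == 0:
        raise ValueError("zero variance in areas or CVs")
    r, p = scipy.stats.pearsonr(np.log(a), c)
    return float(r), float(p)


def median_and_range(values, lo_pct: float = 5.0, hi_pct: float = 95.0):
    """Median and central 90% range (5th-95th percentiles) of a sample."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan"), float("nan")
    return (
        float(np.median(v)),
        float(np.percentile(v, lo_pct)),
        float(np.percentile(v, hi_pct)),
    )
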