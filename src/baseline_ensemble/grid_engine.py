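"""Method-grid enumeration and baseline computation.

A *method combination* is one cell of the grid: projection approach x
forest dataset variant x reference length x start year x carbon mask x
AGB source x BGB source x SOC source.  For every jurisdiction and valid
combination the deforestation emission baseline is the product of the
projected deforestation rate (km2/yr) and the average forest carbon
density (tCO2e/km2); relative uncertainties of the two factors combine in
quadrature.  Driver-model fits are cached per (approach, scope, variant,
window) so each model is fitted once and reused across jurisdictions.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError, GridConfig
from .synthetic_data import JurisdictionPanel
from . import projection as proj

__all__ = [
    "enumerate_combinations",
    "count_combinations",
    "combination_id",
    "propagate_uncertainty",
    "compute_baseline",
    "compute_projections",
    "merge_baselines",
    "run_grid",
]

log = logging.getLogger(__name__)

RATE_KEYS = ["approach", "defor_variant", "ref_length", "start_year"]
CARBON_KEYS = ["carbon_mask_variant", "agb_source", "bgb_source", "soc_source"]
COMBO_FIELDS = RATE_KEYS + CARBON_KEYS


def _valid_windows(
    span: tuple[int, int],
    ref_lengths: Sequence[int],
    start_years: Sequence[int] | None,
) -> list[tuple[int, int]]:
    """(start_year, length) pairs whose window fits entirely in the span."""
    y0, y1 = span
    out = []
    for length in ref_lengths:
        starts = range(y0, y1 - length + 2) if start_years is None else start_years
        for s in starts:
            if s >= y0 and s + length - 1 <= y1:
                out.append((int(s), int(length)))
    return out


def combination_id(fields: Sequence[object]) -> str:
    """Stable 12-hex-digit id over all combination fields."""
    key = "|".join(str(f) for f in fields)
    return hashlib.sha1(key.encode("utf-8")).hexdigest()[:12]


def enumerate_combinations(
    grid: GridConfig, variant_spans: Mapping[str, tuple[int, int]]
) -> pd.DataFrame:
    """Materialise the Cartesian method grid, filtered to window-valid
    cells, in deterministic order, one row per combination."""
    grid.validate()
    rows = []
    for approach in grid.approaches:
        for variant in grid.defor_variants:
            span = variant_spans.get(variant)
            if span is None:
                raise ConfigurationError(f"no span for variant {variant!r}")
            for start, length in _valid_windows(span, grid.ref_lengths, grid.start_years):
                for mask, agb, bgb, soc in itertools.product(
                    grid.carbon_mask_variants,
                    grid.agb_sources,
                    grid.bgb_sources,
                    grid.soc_sources,
                ):
                    rows.append((approach, variant, length, start, mask, agb, bgb, soc))
    if not rows:
        raise ConfigurationError("method grid is empty")
    df = pd.DataFrame(rows, columns=COMBO_FIELDS)
    df.insert(0, "combination_id", [combination_id(r) for r in rows])
    return df


def count_combinations(
    grid: GridConfig,
    variant_spans: Mapping[str, tuple[int, int]],
    n_jurisdictions: int = 1,
) -> int:
    """Combination count by arithmetic (no materialisation), so the full
    study-scale grid (order 1e9 across thousands of jurisdictions) can be
    sized without computing any baseline."""
    grid.validate()
    n_windows = sum(
        len(_valid_windows(variant_spans[v], grid.ref_lengths, grid.start_years))
        for v in grid.defor_variants
    )
    n_carbon = (
        len(grid.carbon_mask_variants)
        * len(grid.agb_sources)
        * len(grid.bgb_sources)
        * len(grid.soc_sources)
    )
    return len(grid.approaches) * n_windows * n_carbon * n_jurisdictions


# ---------------------------------------------------------------------------
# uncertainty propagation and single-record assembly


def propagate_uncertainty(rate_rel_u: float, carbon_rel_u: float) -> float:
    """Quadrature combination of the two factor uncertainties.

    Either input NaN (e.g. the uncertainty-free ``hist`` approach)
    propagates to NaN: such records carry no overall uncertainty rather
    than a substitute value.
    """
    if np.isnan(rate_rel_u) or np.isnan(carbon_rel_u):
        return float("nan")
    if rate_rel_u < 0 or carbon_rel_u < 0:
        raise ValueError("relative uncertainties must be >= 0")
    return float(np.sqrt(rate_rel_u**2 + carbon_rel_u**2))


def compute_baseline(
    jurisdiction_id: str,
    combination: Mapping[str, object],
    projection_result: proj.ProjectionResult,
    carbon_density_t_km2: float,
    carbon_rel_u: float,
) -> dict:
    """One BaselineRecord: baseline = projected rate x carbon density.

    Invalid (negative-rate) projections yield a flagged record that is
    retained for audit but excluded from every downstream statistic.
    """
    valid = bool(projection_result.valid) and carbon_density_t_km2 >= 0
    rate = projection_result.point_rate
    return {
        "jurisdiction_id": jurisdiction_id,
        "combination_id": combination_id([combination[k] for k in COMBO_FIELDS]),
        **{k: combination[k] for k in COMBO_FIELDS},
        "projected_rate": rate,
        "carbon_density": carbon_density_t_km2,
        "baseline": rate * carbon_density_t_km2 if valid else float("nan"),
        "rate_rel_u": projection_result.relative_uncertainty,
        "carbon_rel_u": carbon_rel_u,
        "propagated_rel_u": propagate_uncertainty(
            projection_result.relative_uncertainty, carbon_rel_u
        ),
        "valid": valid,
    }


# ---------------------------------------------------------------------------
# grid execution


def _window_driver_means(
    panel: JurisdictionPanel, window: tuple[int, int]
) -> pd.Series:
    years = np.arange(window[0], window[0] + window[1])
    return panel.drivers_by_year.loc[panel.drivers_by_year.index.intersection(years)].mean()


def compute_projections(
    panels: Sequence[JurisdictionPanel],
    grid: GridConfig,
    variant_spans: Mapping[str, tuple[int, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Projected rate for every jurisdiction x (approach, variant, window).

    Driver models and ensembles are fitted once per (approach, scope,
    variant, window) cell and reused for every jurisdiction in scope; fit
    failures (e.g. a region with fewer jurisdictions than parameters) mark
    the affected records invalid with a reason instead of aborting.
    """
    grid.validate()
    records: list[dict] = []

    def emit(panel, approach, variant, window, result, reason=""):
        if result is not None:
            result = proj.screen_nonnegative(result)
            reason = "" if result.valid else "negative_rate"
        records.append(
            {
                "jurisdiction_id": panel.jurisdiction_id,
                "approach": approach,
                "defor_variant": variant,
                "ref_length": window[1],
                "start_year": window[0],
                "point_rate": result.point_rate if result else float("nan"),
                "pi_lower": result.pi_lower if result else float("nan"),
                "pi_upper": result.pi_upper if result else float("nan"),
                "rate_rel_u": result.relative_uncertainty if result else float("nan"),
                "valid": bool(result.valid) if result else False,
                "reason": reason,
            }
        )

    regions = sorted({p.region for p in panels})
    for variant in grid.defor_variants:
        span = variant_spans[variant]
        for window in _valid_windows(span, grid.ref_lengths, grid.start_years):
            driver_means = {
                p.jurisdiction_id: _window_driver_means(p, window) for p in panels
            }
            for approach in grid.approaches:
                if approach in ("hist", "linear", "poly2"):
                    for p in panels:
                        series = p.defor_by_variant[variant]
                        try:
                            if approach == "hist":
                                r = proj.project_historical_average(series, window)
                            else:
                                r = proj.project_time_function(
                                    series, window, 1 if approach == "linear" else 2
                                )
                            emit(p, approach, variant, window, r)
                        except (proj.RangeError, proj.FitError) as e:
                            emit(p, approach, variant, window, None, type(e).__name__)
                    continue

                scopes = (
                    ["global"] if approach in ("global", "global_s") else regions
                )
                ensemble = approach.endswith("_s")
                for scope in scopes:
                    in_scope = [
                        p for p in panels if scope == "global" or p.region == scope
                    ]
                    model = None
                    err = ""
                    try:
                        if ensemble:
                            model = proj.fit_ensemble(
                                panels,
                                scope,
                                variant,
                                window,
                                reps=grid.ensemble_reps,
                                size_range=grid.ensemble_size_range,
                                seed=seed,
                                member_stepwise=grid.member_stepwise,
                                min_fit_margin=grid.min_fit_margin,
                            )
                        else:
                            model = proj.fit_driver_model(
                                panels,
                                scope,
                                variant,
                                window,
                                min_fit_margin=grid.min_fit_margin,
                            )
                    except (proj.FitError, proj.EnsembleError) as e:
                        err = f"{type(e).__name__}"
                        log.debug("fit failed %s/%s/%s: %s", scope, variant, window, e)
                    if model is None:
                        for p in in_scope:
                            emit(p, approach, variant, window, None, err)
                        continue
                    exog = pd.DataFrame(
                        {p.jurisdiction_id: driver_means[p.jurisdiction_id] for p in in_scope}
                    ).T
                    try:
                        batch = (
                            proj.predict_ensemble_batch(model, exog, approach)
                            if ensemble
                            else proj.predict_driver_model_batch(model, exog, approach)
                        )
                    except Exception as e:  # pragma: no cover - defensive
                        for p in in_scope:
                            emit(p, approach, variant, window, None, type(e).__name__)
                        continue
                    for p in in_scope:
                        b = batch.loc[p.jurisdiction_id]
                        r = proj.ProjectionResult(
                            point_rate=float(b["point_rate"]),
                            pi_lower=float(b["pi_lower"]),
                            pi_upper=float(b["pi_upper"]),
                            relative_uncertainty=float(b["relative_uncertainty"]),
                            approach=approach,
                        )
                        emit(p, approach, variant, window, r)

    df = pd.DataFrame(records)
    return df.sort_values(
        ["jurisdiction_id", "approach", "defor_variant", "ref_length", "start_year"]
    ).reset_index(drop=True)


def merge_baselines(
    combos: pd.DataFrame,
    projections: pd.DataFrame,
    carbon_estimates: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the BaselineRecord table from the factor tables.

    ``combos x jurisdictions`` resolves the rate through the projections
    table (keyed by approach/variant/window) and the density through the
    carbon table (keyed by jurisdiction/mask/sources); baseline = rate x
    density, uncertainty in quadrature.
    """
    carbon_keyed = carbon_estimates.rename(
        columns={
            "mask_variant": "carbon_mask_variant",
            "agb_source": "agb_source",
        }
    )
    df = combos.merge(projections, on=RATE_KEYS, how="inner")
    df = df.merge(
        carbon_keyed, on=["jurisdiction_id"] + CARBON_KEYS, how="inner"
    )
    df["valid"] = (
        df["valid"]
        & np.isfinite(df["co2e_per_km2"].to_numpy(dtype=float))
        & np.isfinite(df["point_rate"].to_numpy(dtype=float))
    )
    df["baseline"] = np.where(
        df["valid"], df["point_rate"] * df["co2e_per_km2"], np.nan
    )
    df["propagated_rel_u"] = np.sqrt(df["rate_rel_u"] ** 2 + df["carbon_rel_u"] ** 2)
    df = df.rename(
        columns={"point_rate": "projected_rate", "co2e_per_km2": "carbon_density"}
    )
    cols = (
        ["jurisdiction_id", "combination_id"]
        + COMBO_FIELDS
        + [
            "projected_rate", "carbon_density", "baseline",
            "rate_rel_u", "carbon_rel_u", "agb_rel_u", "bgb_rel_u",
            "propagated_rel_u", "valid",
        ]
    )
    return (
        df[cols]
        .sort_values(["jurisdiction_id", "combination_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def run_grid(
    panels: Sequence[JurisdictionPanel],
    carbon_estimates: pd.DataFrame,
    grid: GridConfig,
    variant_spans: Mapping[str, tuple[int, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """End-to-end grid pass: projections + enumeration + baseline table."""
    combos = enumerate_combinations(grid, variant_spans)
    projections = compute_projections(panels, grid, variant_spans, seed=seed)
    return merge_baselines(combos, projections, carbon_estimates)
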