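"""Seeded synthetic jurisdictions with known ground truth.

Real baseline sensitivity studies extract annual forest-loss areas from
several global forest-change products, driver covariates, and carbon
densities from several biomass/soil products.  This module generates data
with the same statistical structure so that every downstream stage can be
tested against a known truth:

* a latent annual deforestation process per jurisdiction,
  ``log rate_t = intercept + beta . x_t + AR(1) noise``, which keeps rates
  positive and lets regression stages be checked by parameter recovery;
* five dataset *variants* observing the latent series, each with its own
  calendar span, multiplicative bias and lognormal observation noise
  (three tree-cover-threshold variants of one product share a span);
* forest-stock series per variant obeying the clipping rule that a year's
  loss cannot exceed the previous year's stock and stocks never increase;
* per-source carbon densities (AGB/BGB biomass, SOC) with differing
  relative uncertainties, including a sparse-sampling source that observes
  only a fraction of equal-area sub-units, and a BGB source expressed as a
  root:shoot ratio of AGB;
* subnational children for large jurisdictions, produced by partitioning
  the national latent series with a Dirichlet share vector.

All randomness flows from one root seed through named streams keyed by
jurisdiction / variant / source, so regenerating with the same config and
seed is bit-identical and adding jurisdictions never perturbs existing
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .config import (
    DRIVER_NAMES,
    ConfigurationError,
    GeneratorConfig,
)

__all__ = [
    "JurisdictionPanel",
    "GroundTruth",
    "DataError",
    "generate_panels",
    "generate_carbon_layers",
    "generate_dataset",
    "screen_jurisdictions",
    "panels_to_frames",
    "frames_to_panels",
]


class DataError(ValueError):
    """Raised when input data violate a structural requirement."""


@dataclass
class JurisdictionPanel:
    """One jurisdiction's annual panel across all dataset variants."""

    jurisdiction_id: str
    admin_level: str  # "national" | "subnational"
    region: str
    land_area_km2: float
    forest_area0_km2: float
    #: per variant: year-indexed end-of-year forest stock (km2)
    forest_by_variant: dict[str, pd.Series]
    #: per variant: year-indexed annual loss (km2/yr)
    defor_by_variant: dict[str, pd.Series]
    #: year-indexed driver covariates (standardised scale)
    drivers_by_year: pd.DataFrame
    parent_id: str | None = None
    children_ids: tuple[str, ...] = ()

    def reference_forest_km2(self, variant: str) -> float:
        """Forest stock at the start of the variant's first year."""
        f = self.forest_by_variant[variant]
        d = self.defor_by_variant[variant]
        return float(f.iloc[0] + d.iloc[0])

    @property
    def cover_fraction(self) -> float:
        if not np.isfinite(self.land_area_km2) or self.land_area_km2 <= 0:
            raise DataError(f"{self.jurisdiction_id}: missing land area")
        return self.forest_area0_km2 / self.land_area_km2


@dataclass
class GroundTruth:
    """Latent quantities behind one generated panel."""

    jurisdiction_id: str
    latent_rate_by_year: pd.Series  # km2/yr, union span
    intercept: float
    true_driver_coefficients: np.ndarray
    #: per-source true mean density (Mg/ha biomass, Mg C/ha for SOC);
    #: ratio sources store the ratio itself
    true_carbon_density: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generation


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _observe_variant(
    latent: pd.Series,
    span: tuple[int, int],
    bias: float,
    cv: float,
    forest0: float,
    rng: np.random.Generator,
) -> tuple[pd.Series, pd.Series]:
    """Observe the latent series through one dataset variant.

    Applies the variant's multiplicative bias and lognormal noise, then
    enforces the stock-consistency clip: loss in year t cannot exceed the
    stock at the end of year t-1, and stocks never increase.
    """
    years = np.arange(span[0], span[1] + 1)
    obs = latent.loc[years].to_numpy() * bias * _lognormal_noise(rng, cv, len(years))
    forest = np.empty(len(years))
    defor = np.empty(len(years))
    prev = forest0
    for i in range(len(years)):
        defor[i] = min(obs[i], prev)
        forest[i] = prev - defor[i]
        prev = forest[i]
    return (
        pd.Series(forest, index=years, name="forest_km2"),
        pd.Series(defor, index=years, name="defor_km2"),
    )


def _make_drivers(
    rng: np.random.Generator,
    years: np.ndarray,
    n_drivers: int,
    common_loading: float = 0.0,
    drift_sd: float = 0.05,
) -> pd.DataFrame:
    factor = rng.normal(0.0, 1.0)
    base = rng.normal(0.0, 1.0, size=n_drivers)
    if common_loading:
        base = common_loading * factor + np.sqrt(1.0 - common_loading**2) * base
    drift = drift_sd * np.cumsum(rng.normal(0.0, 1.0, size=(len(years), n_drivers)), axis=0)
    return pd.DataFrame(base + drift, index=years, columns=list(DRIVER_NAMES[:n_drivers]))


def _generate_unit(
    config: GeneratorConfig,
    jid: str,
    region: str,
    forest0: float,
    land_area: float,
    latent: pd.Series | None,
    drivers: pd.DataFrame,
    intercept: float,
    beta: np.ndarray,
    admin_level: str,
    parent_id: str | None,
) -> tuple[JurisdictionPanel, GroundTruth]:
    """Build a panel from an (optionally pre-partitioned) latent series."""
    y0, y1 = config.union_span
    years = np.arange(y0, y1 + 1)

    if latent is None:
        rng = stream(config.seed, "latent", jid)
        phi, sd = config.ar1_coefficient, config.process_noise_sd
        eps = np.empty(len(years))
        eps[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2)) if sd > 0 else 0.0
        innov = rng.normal(0.0, sd, size=len(years) - 1) if sd > 0 else np.zeros(len(years) - 1)
        for t in range(1, len(years)):
            eps[t] = phi * eps[t - 1] + innov[t - 1]
        x = drivers.to_numpy()
        latent = pd.Series(np.exp(intercept + x @ beta + eps), index=years)

    forest_by_variant: dict[str, pd.Series] = {}
    defor_by_variant: dict[str, pd.Series] = {}
    for variant, span in config.variant_spans.items():
        cv = config.observation_noise_cv.get(variant, 0.0)
        if config.noise_area_scaling:
            cv = cv * np.sqrt(config.noise_area_reference_km2 / forest0)
        rng_v = stream(config.seed, "obs", jid, variant)
        forest, defor = _observe_variant(
            latent,
            span,
            config.dataset_bias_factors.get(variant, 1.0),
            cv,
            forest0,
            rng_v,
        )
        forest_by_variant[variant] = forest
        defor_by_variant[variant] = defor

    panel = JurisdictionPanel(
        jurisdiction_id=jid,
        admin_level=admin_level,
        region=region,
        land_area_km2=land_area,
        forest_area0_km2=forest0,
        forest_by_variant=forest_by_variant,
        defor_by_variant=defor_by_variant,
        drivers_by_year=drivers,
        parent_id=parent_id,
    )
    truth = GroundTruth(
        jurisdiction_id=jid,
        latent_rate_by_year=latent,
        intercept=intercept,
        true_driver_coefficients=beta.copy(),
    )
    return panel, truth


def generate_panels(
    config: GeneratorConfig,
) -> list[tuple[JurisdictionPanel, GroundTruth]]:
    """Generate ``n_jurisdictions`` national panels (plus subnational
    children for those above the subdivision threshold).

    Returns panels paired with their ground truth, in a deterministic
    order: nationals by index, each followed by its children.
    """
    config.validate()
    beta = np.asarray(config.driver_effect_sizes, dtype=float)
    y0, y1 = config.union_span
    years = np.arange(y0, y1 + 1)
    out: list[tuple[JurisdictionPanel, GroundTruth]] = []

    for i in range(config.n_jurisdictions):
        jid = f"J{i:04d}"
        rng = stream(config.seed, "jur", jid)
        region = str(rng.choice(list(config.region_labels)))
        lo, hi = config.forest_area_range_km2
        forest0 = float(
            np.clip(
                config.forest_area_median_km2
                * np.exp(rng.normal(0.0, config.forest_area_sigma)),
                lo,
                hi,
            )
        )
        cover = float(rng.uniform(*config.cover_range))
        land_area = forest0 / cover
        drivers = _make_drivers(
            stream(config.seed, "drivers", jid),
            years,
            config.n_drivers,
            config.driver_common_factor_loading,
            config.driver_drift_sd,
        )
        intercept = float(np.log(config.base_deforestation_fraction * forest0))

        panel, truth = _generate_unit(
            config, jid, region, forest0, land_area, None, drivers,
            intercept, beta, "national", None,
        )
        children: list[tuple[JurisdictionPanel, GroundTruth]] = []
        if forest0 > config.subdivision_threshold_km2:
            rng_c = stream(config.seed, "children", jid)
            k = int(rng_c.integers(config.children_range[0], config.children_range[1] + 1))
            shares = rng_c.dirichlet(np.full(k, config.dirichlet_alpha))
            cover_wiggle = np.clip(
                cover * np.exp(rng_c.normal(0.0, 0.35, size=k)), 0.02, 0.95
            )
            for c in range(k):
                cid = f"{jid}-S{c}"
                child_latent = truth.latent_rate_by_year * shares[c]
                child_forest0 = forest0 * shares[c]
                child_land = child_forest0 / cover_wiggle[c]
                child_drivers = drivers + stream(config.seed, "childdrv", cid).normal(
                    0.0, 0.2, size=config.n_drivers
                )
                cp, ct = _generate_unit(
                    config, cid, region, child_forest0, child_land,
                    child_latent, child_drivers,
                    intercept + float(np.log(shares[c])), beta,
                    "subnational", jid,
                )
                children.append((cp, ct))
            panel.children_ids = tuple(cp.jurisdiction_id for cp, _ in children)
        out.append((panel, truth))
        out.extend(children)
    return out


# ---------------------------------------------------------------------------
# carbon layers


def generate_carbon_layers(
    config: GeneratorConfig, panel: JurisdictionPanel, truth: GroundTruth | None = None
) -> pd.DataFrame:
    """Per-source carbon observations for one jurisdiction.

    Returns one row per (mask_variant, source) with columns
    ``jurisdiction_id, mask_variant, source, pool, kind, value,
    rel_uncertainty``.  Dense sources report a jurisdiction mean density;
    the sparse source reports the mean over a sampled fraction of the
    jurisdiction's equal-area sub-units with correspondingly inflated
    uncertainty; ratio sources report the regional root:shoot ratio.
    ``rel_uncertainty`` is NaN when the provider publishes none (the carbon
    module then applies the 33% default).
    """
    sources = config.carbon_source_params
    n_agb = sum(1 for s in sources.values() if s.pool == "agb")
    n_bgb = sum(1 for s in sources.values() if s.pool == "bgb")
    n_soc = sum(1 for s in sources.values() if s.pool == "soc")
    if n_agb < 3 or n_bgb < 3 or n_soc < 2:
        raise ConfigurationError(
            "carbon_source_params needs >=3 AGB, >=3 BGB (one ratio), >=2 SOC sources"
        )
    if not 0 < config.sparse_source_sampling_fraction <= 1:
        raise ConfigurationError("sparse_source_sampling_fraction must be in (0, 1]")

    jid = panel.jurisdiction_id
    rows = []
    for name, spec in sources.items():
        rng = stream(config.seed, "carbon", jid, name)
        if spec.kind == "ratio":
            if spec.ratio_by_region is None:
                raise ConfigurationError(f"ratio source {name!r} has no ratio table")
            ratio = spec.ratio_by_region[panel.region]
            if truth is not None:
                truth.true_carbon_density[name] = ratio
            for mask in config.variants:
                rows.append((jid, mask, name, spec.pool, "ratio", ratio, spec.rel_uncertainty))
            continue

        d_true = spec.mean_density * float(
            _lognormal_noise(rng, config.carbon_between_jurisdiction_cv, ())
        )
        if truth is not None:
            truth.true_carbon_density[name] = d_true
        if spec.kind == "sparse":
            cells = d_true * _lognormal_noise(rng, config.carbon_cell_cv, config.n_carbon_subunits)
            k = max(1, int(round(config.sparse_source_sampling_fraction * config.n_carbon_subunits)))
            sample = cells[rng.choice(config.n_carbon_subunits, size=k, replace=False)]
            est = float(np.mean(sample))
            rel_se = (
                float(np.std(sample, ddof=1) / (np.sqrt(k) * est))
                if k > 1 and est > 0
                else 0.0
            )
            base_u = spec.rel_uncertainty if spec.rel_uncertainty is not None else np.nan
            u = float(np.sqrt(np.nansum([base_u**2, rel_se**2]))) if not np.isnan(base_u) else rel_se
            if u == 0 and not np.isnan(base_u):
                u = base_u
            value = est
            rel_u: float | None = u if (u and u > 0) else base_u
        else:
            value = d_true
            rel_u = spec.rel_uncertainty
        for mask in config.variants:
            mask_factor = float(
                _lognormal_noise(stream(config.seed, "mask", jid, name, mask),
                                 config.carbon_mask_cv, ())
            )
            rows.append((jid, mask, name, spec.pool, spec.kind, value * mask_factor, rel_u))

    return pd.DataFrame(
        rows,
        columns=[
            "jurisdiction_id", "mask_variant", "source", "pool", "kind",
            "value", "rel_uncertainty",
        ],
    ).astype({"value": float, "rel_uncertainty": float})


# ---------------------------------------------------------------------------
# screening


def screen_jurisdictions(
    panels: list[JurisdictionPanel],
    reference_variant: str,
    min_forest_km2: float = 1000.0,
    subdivide_above_km2: float = 10000.0,
    min_cover_fraction: float = 0.10,
) -> list[JurisdictionPanel]:
    """Apply the jurisdiction inclusion rules.

    National units need at least ``min_forest_km2`` of forest (as estimated
    by the reference variant in its first year); those above
    ``subdivide_above_km2`` are replaced by their subnational children;
    subnational units below ``min_cover_fraction`` forest cover are dropped.
    """
    by_id = {p.jurisdiction_id: p for p in panels}
    retained: list[JurisdictionPanel] = []
    for p in panels:
        if p.admin_level != "national":
            continue
        if reference_variant not in p.forest_by_variant:
            raise DataError(f"{p.jurisdiction_id}: no variant {reference_variant!r}")
        forest = p.reference_forest_km2(reference_variant)
        if forest < min_forest_km2:
            continue
        if forest > subdivide_above_km2 and p.children_ids:
            for cid in p.children_ids:
                child = by_id.get(cid)
                if child is None:
                    raise DataError(f"{p.jurisdiction_id}: missing child {cid!r}")
                if child.cover_fraction >= min_cover_fraction:
                    retained.append(child)
        else:
            retained.append(p)
    return retained


# ---------------------------------------------------------------------------
# tabular export


def panels_to_frames(
    pairs: list[tuple[JurisdictionPanel, GroundTruth]]
) -> dict[str, pd.DataFrame]:
    """Flatten generated panels into the long-format output tables.

    Returns ``panels`` (jurisdiction_id, variant, year, forest_km2,
    defor_km2), ``jurisdictions`` (metadata), ``drivers`` (jurisdiction_id,
    year, one column per driver) and ``ground_truth`` (long: kind/key/value
    holding latent rates, intercepts, coefficients and carbon densities).
    """
    panel_rows, meta_rows, driver_frames, truth_rows = [], [], [], []
    for panel, truth in pairs:
        for variant in panel.forest_by_variant:
            f = panel.forest_by_variant[variant]
            d = panel.defor_by_variant[variant]
            for year in f.index:
                panel_rows.append(
                    (panel.jurisdiction_id, variant, int(year), f.loc[year], d.loc[year])
                )
        meta_rows.append(
            (
                panel.jurisdiction_id,
                panel.admin_level,
                panel.parent_id or "",
                panel.region,
                panel.land_area_km2,
                panel.forest_area0_km2,
            )
        )
        dv = panel.drivers_by_year.reset_index(names="year")
        dv.insert(0, "jurisdiction_id", panel.jurisdiction_id)
        driver_frames.append(dv)
        for year, rate in truth.latent_rate_by_year.items():
            truth_rows.append((truth.jurisdiction_id, "latent_rate", str(int(year)), rate))
        truth_rows.append((truth.jurisdiction_id, "intercept", "", truth.intercept))
        for dname, coef in zip(DRIVER_NAMES, truth.true_driver_coefficients):
            truth_rows.append((truth.jurisdiction_id, "coefficient", dname, coef))
        for sname, dens in truth.true_carbon_density.items():
            truth_rows.append((truth.jurisdiction_id, "carbon_density", sname, dens))
    return {
        "panels": pd.DataFrame(
            panel_rows,
            columns=["jurisdiction_id", "variant", "year", "forest_km2", "defor_km2"],
        ),
        "jurisdictions": pd.DataFrame(
            meta_rows,
            columns=[
                "jurisdiction_id", "admin_level", "parent_id", "region",
                "land_area_km2", "forest_area0_km2",
            ],
        ),
        "drivers": pd.concat(driver_frames, ignore_index=True),
        "ground_truth": pd.DataFrame(
            truth_rows, columns=["jurisdiction_id", "kind", "key", "value"]
        ),
    }


def frames_to_panels(
    panels_df: pd.DataFrame,
    jurisdictions_df: pd.DataFrame,
    drivers_df: pd.DataFrame,
) -> list[JurisdictionPanel]:
    """Rebuild panel objects from the long-format tables (inverse of
    :func:`panels_to_frames`, minus ground truth)."""
    children: dict[str, list[str]] = {}
    meta = {}
    for row in jurisdictions_df.itertuples(index=False):
        meta[row.jurisdiction_id] = row
        parent = row.parent_id if isinstance(row.parent_id, str) and row.parent_id else None
        if parent:
            children.setdefault(parent, []).append(row.jurisdiction_id)
    drivers_by_jur = {
        jid: g.drop(columns="jurisdiction_id").set_index("year").sort_index()
        for jid, g in drivers_df.groupby("jurisdiction_id", sort=False)
    }
    panels = []
    for jid, g in panels_df.groupby("jurisdiction_id", sort=False):
        m = meta[jid]
        forest_by_variant, defor_by_variant = {}, {}
        for variant, gv in g.groupby("variant", sort=False):
            gv = gv.sort_values("year")
            idx = gv["year"].to_numpy()
            forest_by_variant[variant] = pd.Series(
                gv["forest_km2"].to_numpy(), index=idx, name="forest_km2"
            )
            defor_by_variant[variant] = pd.Series(
                gv["defor_km2"].to_numpy(), index=idx, name="defor_km2"
            )
        parent = m.parent_id if isinstance(m.parent_id, str) and m.parent_id else None
        panels.append(
            JurisdictionPanel(
                jurisdiction_id=jid,
                admin_level=m.admin_level,
                region=m.region,
                land_area_km2=float(m.land_area_km2),
                forest_area0_km2=float(m.forest_area0_km2),
                forest_by_variant=forest_by_variant,
                defor_by_variant=defor_by_variant,
                drivers_by_year=drivers_by_jur[jid],
                parent_id=parent,
                children_ids=tuple(children.get(jid, ())),
            )
        )
    return panels


def generate_dataset(config: GeneratorConfig) -> dict[str, pd.DataFrame]:
    """Full generation pass: panels, metadata, drivers, truth and carbon
    observation tables, as DataFrames keyed like the CSV outputs."""
    pairs = generate_panels(config)
    carbon = pd.concat(
        [generate_carbon_layers(config, p, t) for p, t in pairs], ignore_index=True
    )
    frames = panels_to_frames(pairs)
    frames["carbon_sources"] = carbon
    return frames
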