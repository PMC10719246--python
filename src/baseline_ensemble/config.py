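"""Configuration objects for the synthetic study and the method grid.

The study enumerates every permitted combination of

* deforestation projection approach (7 levels),
* forest-change dataset variant (5 levels),
* historical reference period length (5-15 years) and starting year,
* forest mask used for carbon estimation (5 levels),
* aboveground biomass (AGB), belowground biomass (BGB) and soil organic
  carbon (SOC) source (3 x 3 x 2 levels),

computes a deforestation emission baseline (tCO2e/yr) for each jurisdiction
under each combination, and summarises variability, hindcast accuracy and
propagated uncertainty.  The configuration below controls both the
synthetic jurisdiction generator and the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DRIVER_NAMES",
    "REGIONS",
    "DEFAULT_VARIANT_SPANS",
    "CarbonSourceSpec",
    "GeneratorConfig",
    "GridConfig",
    "RunConfig",
    "ConfigurationError",
    "load_config",
    "save_config",
    "default_small_config",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


#: Driver covariates on the log deforestation rate (synthetic analogues of
#: the usual biophysical / socioeconomic predictors; values are generated on
#: a standardised scale, the names fix the column order everywhere).
DRIVER_NAMES: tuple[str, ...] = (
    "elevation",
    "slope",
    "temperature",
    "precipitation",
    "gdp",
    "hdi",
    "nightlights",
    "pop_density",
    "pct_forest",
    "pct_agriculture",
    "pct_mining",
    "pct_plantations",
)

REGIONS: tuple[str, ...] = (
    "Africa",
    "Asia",
    "Oceania",
    "Latin America",
    "North America",
    "Europe",
)

#: Calendar spans (first_year, last_year), both inclusive, of the five
#: forest-change dataset variants: three tree-cover-threshold variants of
#: one 30 m product sharing a 2000-2021 span, a 500 m product (2001-2020)
#: and a 300 m product (1992-2020).
DEFAULT_VARIANT_SPANS: dict[str, tuple[int, int]] = {
    "hansen15": (2000, 2021),
    "hansen30": (2000, 2021),
    "hansen60": (2000, 2021),
    "modis": (2001, 2020),
    "esacci": (1992, 2020),
}

#: Minimum span length so that the longest reference window (15 yr) fits.
MIN_SPAN_YEARS = 16


@dataclass
class CarbonSourceSpec:
    """One carbon data source.

    pool
        ``"agb"`` / ``"bgb"`` (biomass, Mg/ha) or ``"soc"`` (carbon, Mg C/ha).
    kind
        ``"dense"`` — wall-to-wall mean density; ``"sparse"`` — sampled from
        a fraction of sub-units (GEDI-track style) with correspondingly
        inflated uncertainty; ``"ratio"`` — BGB expressed as a root:shoot
        ratio of the combination's AGB source.
    mean_density
        Global mean density (Mg/ha) around which jurisdiction means vary;
        unused for ``ratio`` sources.
    rel_uncertainty
        Provider relative uncertainty (1-sigma-like, dimensionless); ``None``
        means the provider publishes none and the 33% default applies.
    ratio_by_region
        For ``ratio`` sources: region -> root:shoot ratio.
    """

    pool: str
    kind: str = "dense"
    mean_density: float = 0.0
    rel_uncertainty: float | None = None
    ratio_by_region: dict[str, float] | None = None


def _default_carbon_sources() -> dict[str, CarbonSourceSpec]:
    # Three AGB sources (one sparse-sampling), three BGB sources (one
    # ratio-of-AGB), two SOC sources.  Densities are typical broadleaf
    # forest magnitudes; uncertainties differ by source on purpose.
    return {
        "spawn": CarbonSourceSpec("agb", "dense", 180.0, 0.13),
        "gedi": CarbonSourceSpec("agb", "sparse", 170.0, 0.15),
        "soto": CarbonSourceSpec("agb", "dense", 160.0, 0.20),
        "spawn_bgb": CarbonSourceSpec("bgb", "dense", 45.0, 0.25),
        "soto_bgb": CarbonSourceSpec("bgb", "dense", 40.0, 0.22),
        "ipcc_ratio": CarbonSourceSpec(
            "bgb",
            "ratio",
            ratio_by_region={
                "Africa": 0.37,
                "Asia": 0.37,
                "Oceania": 0.30,
                "Latin America": 0.37,
                "North America": 0.27,
                "Europe": 0.25,
            },
        ),
        "esdac": CarbonSourceSpec("soc", "dense", 80.0, None),  # 33% default
        "olm": CarbonSourceSpec("soc", "dense", 90.0, 0.30),
    }


@dataclass
class GeneratorConfig:
    """Synthetic jurisdiction generator settings.

    The generator emits, per jurisdiction, a latent annual deforestation
    series driven by covariates, several noisy biased observations of it
    (one per dataset variant), per-source carbon densities, and the ground
    truth needed for parameter-recovery tests.
    """

    n_jurisdictions: int = 20
    seed: int = 0
    variant_spans: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_SPANS)
    )
    n_drivers: int = 12
    n_active_drivers: int = 4
    #: per-driver coefficients on the log latent rate (standardised drivers)
    driver_effect_sizes: tuple[float, ...] | None = None
    #: cross-driver correlation: each driver loads on one latent factor
    #: with this loading (0 = independent drivers, ~1 = near-collinear,
    #: emulating the strong mutual correlation of real covariates)
    driver_common_factor_loading: float = 0.0
    #: per-year random-walk SD of each driver (0 = time-constant drivers)
    driver_drift_sd: float = 0.05
    ar1_coefficient: float = 0.5
    #: innovation SD of the AR(1) term on the log rate
    process_noise_sd: float = 0.3
    #: lognormal observation-noise CV per dataset variant
    observation_noise_cv: dict[str, float] = field(
        default_factory=lambda: {
            "hansen15": 0.05,
            "hansen30": 0.05,
            "hansen60": 0.05,
            "modis": 0.15,
            "esacci": 0.20,
        }
    )
    #: multiplicative observation bias per dataset variant (looser tree-cover
    #: thresholds register more loss area)
    dataset_bias_factors: dict[str, float] = field(
        default_factory=lambda: {
            "hansen15": 1.15,
            "hansen30": 1.00,
            "hansen60": 0.85,
            "modis": 0.90,
            "esacci": 1.10,
        }
    )
    #: mean annual deforestation as a fraction of initial forest area
    base_deforestation_fraction: float = 0.005
    #: lognormal spread of initial forest area across jurisdictions
    forest_area_median_km2: float = 3000.0
    forest_area_sigma: float = 1.2
    forest_area_range_km2: tuple[float, float] = (200.0, 200000.0)
    #: forest cover fraction range (forest / land area)
    cover_range: tuple[float, float] = (0.05, 0.80)
    #: if True, observation noise CV scales as cv * sqrt(ref_area / forest),
    #: so small jurisdictions are observed more noisily
    noise_area_scaling: bool = False
    noise_area_reference_km2: float = 3000.0
    carbon_source_params: dict[str, CarbonSourceSpec] = field(
        default_factory=_default_carbon_sources
    )
    #: between-jurisdiction CV of true mean carbon density
    carbon_between_jurisdiction_cv: float = 0.30
    #: within-jurisdiction CV of sub-unit (cell) densities for sparse sources
    carbon_cell_cv: float = 0.30
    sparse_source_sampling_fraction: float = 0.05
    n_carbon_subunits: int = 1000
    #: mask-to-mask CV of jurisdiction mean density (different forest masks
    #: average carbon over slightly different pixels)
    carbon_mask_cv: float = 0.03
    region_labels: tuple[str, ...] = REGIONS
    #: jurisdictions above this forest area get subnational children
    subdivision_threshold_km2: float = 10000.0
    children_range: tuple[int, int] = (3, 8)
    dirichlet_alpha: float = 1.5

    def __post_init__(self) -> None:
        if self.driver_effect_sizes is None:
            base = (0.8, -0.6, 0.5, -0.4, 0.3, -0.3, 0.25, -0.25, 0.2, -0.2, 0.15, 0.15)
            eff = [0.0] * self.n_drivers
            for i in range(min(self.n_active_drivers, self.n_drivers)):
                eff[i] = base[i % len(base)]
            self.driver_effect_sizes = tuple(eff)

    def validate(self) -> None:
        if self.n_jurisdictions < 1:
            raise ConfigurationError("n_jurisdictions must be >= 1")
        for name, (y0, y1) in self.variant_spans.items():
            if y1 - y0 + 1 < MIN_SPAN_YEARS:
                raise ConfigurationError(
                    f"variant {name!r} span {y0}-{y1} shorter than "
                    f"{MIN_SPAN_YEARS} years"
                )
        for name, cv in self.observation_noise_cv.items():
            if cv < 0:
                raise ConfigurationError(f"observation_noise_cv[{name!r}] < 0")
        for name, b in self.dataset_bias_factors.items():
            if b <= 0:
                raise ConfigurationError(f"dataset_bias_factors[{name!r}] <= 0")
        if not 0 <= self.ar1_coefficient < 1:
            raise ConfigurationError("ar1_coefficient must be in [0, 1)")
        if self.n_active_drivers > self.n_drivers:
            raise ConfigurationError("n_active_drivers > n_drivers")
        eff = np.asarray(self.driver_effect_sizes, dtype=float)
        if eff.size != self.n_drivers or not np.all(np.isfinite(eff)):
            raise ConfigurationError(
                "driver_effect_sizes must be n_drivers finite values"
            )
        if not 0 < self.sparse_source_sampling_fraction <= 1:
            raise ConfigurationError("sparse_source_sampling_fraction must be in (0, 1]")

    @property
    def union_span(self) -> tuple[int, int]:
        y0 = min(s[0] for s in self.variant_spans.values())
        y1 = max(s[1] for s in self.variant_spans.values())
        return y0, y1

    @property
    def variants(self) -> tuple[str, ...]:
        return tuple(self.variant_spans)


@dataclass
class GridConfig:
    """Which cells of the method grid to evaluate.

    ``start_years=None`` means every start year for which the reference
    window fits the variant span (the full grid); a list restricts the grid
    to those start years (intersected with validity), which is how the desk
    -scale configurations stay small.
    """

    approaches: tuple[str, ...] = (
        "hist",
        "linear",
        "poly2",
        "global",
        "global_s",
        "regional",
        "regional_s",
    )
    defor_variants: tuple[str, ...] = (
        "hansen15",
        "hansen30",
        "hansen60",
        "modis",
        "esacci",
    )
    ref_lengths: tuple[int, ...] = tuple(range(5, 16))
    start_years: tuple[int, ...] | None = None
    carbon_mask_variants: tuple[str, ...] = (
        "hansen15",
        "hansen30",
        "hansen60",
        "modis",
        "esacci",
    )
    agb_sources: tuple[str, ...] = ("spawn", "gedi", "soto")
    bgb_sources: tuple[str, ...] = ("spawn_bgb", "soto_bgb", "ipcc_ratio")
    soc_sources: tuple[str, ...] = ("esdac", "olm")
    #: multi-model ensemble settings (study scale uses 300 reps)
    ensemble_reps: int = 300
    ensemble_size_range: tuple[int, int] = (3, 11)
    #: apply stepwise elimination inside each random-subset ensemble member
    member_stepwise: bool = False
    #: minimum jurisdictions above parameter count for a driver-model fit
    min_fit_margin: int = 5
    #: belowground decay horizon (years); committed fraction = min(1, h/10)
    bgb_decay_horizon_years: float = 10.0
    soc_inclusion_weight: float = 1.0

    def validate(self) -> None:
        if not (
            self.approaches
            and self.defor_variants
            and self.ref_lengths
            and self.carbon_mask_variants
            and self.agb_sources
            and self.bgb_sources
            and self.soc_sources
        ):
            raise ConfigurationError("grid has an empty parameter level list")
        if min(self.ref_lengths) < 5 or max(self.ref_lengths) > 15:
            raise ConfigurationError("ref_lengths must lie within 5..15")
        lo, hi = self.ensemble_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("invalid ensemble_size_range")


@dataclass
class ImportanceConfig:
    n_models: int = 20
    n_trees: int = 50
    sample_rows: int = 50000
    include_start_year: bool = False
    min_samples_leaf: int = 5


@dataclass
class MetricsConfig:
    uncertainty_threshold_pct: float = 15.0
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Top-level pipeline configuration (one file drives the whole run)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    importance: ImportanceConfig = field(default_factory=ImportanceConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    screening_reference_variant: str = "modis"
    chunk_size: int = 200000

    def validate(self) -> None:
        self.generator.validate()
        self.grid.validate()
        for v in self.grid.defor_variants:
            if v not in self.generator.variant_spans:
                raise ConfigurationError(f"grid variant {v!r} has no span")
        if self.screening_reference_variant not in self.generator.variant_spans:
            raise ConfigurationError("screening_reference_variant has no span")


def default_small_config(n_jurisdictions: int = 20, seed: int = 0) -> RunConfig:
    """Desk-scale configuration: full approach set, trimmed grid."""
    gen = GeneratorConfig(n_jurisdictions=n_jurisdictions, seed=seed)
    grid = GridConfig(
        defor_variants=("hansen30", "modis", "esacci"),
        ref_lengths=(5, 10, 15),
        start_years=(2001, 2004),
        carbon_mask_variants=("hansen30", "modis"),
        ensemble_reps=30,
    )
    imp = ImportanceConfig(n_models=8, n_trees=40, sample_rows=20000)
    return RunConfig(generator=gen, grid=grid, importance=imp)


# ---------------------------------------------------------------------------
# YAML round-trip


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(asdict(cfg)), sort_keys=False))


def _tupled(d: Mapping, keys: Sequence[str]) -> dict:
    out = dict(d)
    for k in keys:
        if k in out and out[k] is not None:
            out[k] = tuple(
                tuple(v) if isinstance(v, list) else v for v in out[k]
            )
    return out


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} did not parse to a mapping")
    gen_raw = _tupled(
        raw.get("generator", {}),
        [
            "driver_effect_sizes",
            "forest_area_range_km2",
            "cover_range",
            "region_labels",
            "children_range",
        ],
    )
    if "variant_spans" in gen_raw:
        gen_raw["variant_spans"] = {
            k: tuple(v) for k, v in gen_raw["variant_spans"].items()
        }
    if "carbon_source_params" in gen_raw:
        gen_raw["carbon_source_params"] = {
            k: CarbonSourceSpec(**v) if isinstance(v, dict) else v
            for k, v in gen_raw["carbon_source_params"].items()
        }
    grid_raw = _tupled(
        raw.get("grid", {}),
        [
            "approaches",
            "defor_variants",
            "ref_lengths",
            "start_years",
            "carbon_mask_variants",
            "agb_sources",
            "bgb_sources",
            "soc_sources",
            "ensemble_size_range",
        ],
    )
    cfg = RunConfig(
        generator=GeneratorConfig(**gen_raw),
        grid=GridConfig(**grid_raw),
        importance=ImportanceConfig(**raw.get("importance", {})),
        metrics=MetricsConfig(**raw.get("metrics", {})),
        screening_reference_variant=raw.get("screening_reference_variant", "modis"),
        chunk_size=int(raw.get("chunk_size", 200000)),
    )
    cfg.validate()
    return cfg
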