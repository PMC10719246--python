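"""Forest carbon density in CO2e and its relative uncertainty.

Average forest carbon per unit area is assembled from three pools:
aboveground biomass (AGB), belowground biomass (BGB, either mapped
directly or derived from AGB by a root:shoot ratio) and soil organic
carbon (SOC).  Biomass is converted to carbon with the 0.47 stoichiometric
factor and carbon to CO2-equivalent with the 3.67 molar-mass factor; SOC
is already carbon so only the molar factor applies.  Belowground carbon
released over a ~10-year decay after deforestation enters through a
committed-emission weight ``min(1, horizon / 10)`` on the BGB pool.

Pool uncertainties come from the data provider where available and
otherwise default to 33%; pool contributions are combined in quadrature:
``u = sqrt(sum (c_i u_i)^2) / sum c_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BIOMASS_TO_CARBON",
    "CARBON_TO_CO2E",
    "IPCC_DEFAULT_UNCERTAINTY",
    "CarbonPools",
    "CarbonEstimate",
    "bgb_from_ratio",
    "default_uncertainty",
    "combine_uncertainties",
    "pools_to_co2e",
    "carbon_estimates_table",
]

#: stoichiometric biomass -> carbon factor
BIOMASS_TO_CARBON = 0.47
#: molar-mass carbon -> CO2e factor (44/12, conventionally printed 3.67)
CARBON_TO_CO2E = 3.67
#: fallback relative uncertainty when the provider publishes none
IPCC_DEFAULT_UNCERTAINTY = 0.33
#: Mg/ha -> t/km2
MG_HA_TO_T_KM2 = 100.0


@dataclass
class CarbonPools:
    """Pool densities (Mg/ha biomass; Mg C/ha for SOC) with uncertainties."""

    agb_biomass: float
    bgb_biomass: float
    soc_carbon: float
    agb_rel_u: float
    bgb_rel_u: float
    soc_rel_u: float

    def validate(self) -> None:
        for v in (self.agb_biomass, self.bgb_biomass, self.soc_carbon):
            if v < 0 or not np.isfinite(v):
                raise ValueError("pool densities must be finite and >= 0")
        for u in (self.agb_rel_u, self.bgb_rel_u, self.soc_rel_u):
            if not (u > 0):
                raise ValueError("pool uncertainties must be > 0")


@dataclass
class CarbonEstimate:
    co2e_density_t_km2: float
    relative_uncertainty: float | None
    decay_weight_applied: float
    #: per-pool CO2e contributions (t/km2), for component summaries
    agb_contribution: float = 0.0
    bgb_contribution: float = 0.0
    soc_contribution: float = 0.0


def bgb_from_ratio(agb_biomass: float, ratio: float) -> float:
    """Belowground biomass from aboveground biomass and a root:shoot ratio."""
    if agb_biomass < 0:
        raise ValueError("agb_biomass must be >= 0")
    if not ratio > 0:
        raise ValueError("ratio must be > 0")
    return agb_biomass * ratio


def default_uncertainty(provider_value: float | None) -> float:
    """Provider relative uncertainty if published, else the 33% default."""
    if provider_value is None or (
        isinstance(provider_value, float) and np.isnan(provider_value)
    ):
        return IPCC_DEFAULT_UNCERTAINTY
    if not provider_value > 0:
        raise ValueError("configured uncertainty must be > 0")
    return float(provider_value)


def combine_uncertainties(
    contributions: np.ndarray | list[float],
    uncertainties: np.ndarray | list[float],
) -> float | None:
    """Relative uncertainty of a sum of independent terms, in quadrature.

    ``sqrt(sum (c_i u_i)^2) / sum c_i``; terms with zero contribution drop
    out.  Returns None when the total contribution is zero (undefined).
    """
    c = np.asarray(contributions, dtype=float)
    u = np.asarray(uncertainties, dtype=float)
    if np.any(c < 0):
        raise ValueError("contributions must be >= 0")
    if np.any(~(u > 0)):
        raise ValueError("uncertainties must be > 0")
    total = c.sum()
    if total == 0:
        return None
    return float(np.sqrt(np.sum((c * u) ** 2)) / total)


def pools_to_co2e(
    pools: CarbonPools,
    bgb_decay_weight: float = 1.0,
    soc_weight: float = 1.0,
) -> CarbonEstimate:
    """Convert pool densities to a CO2e density (t/km2) with uncertainty.

    ``co2e = 3.67 * [0.47 * (agb + w_bgb * bgb) + w_soc * soc]`` (Mg/ha),
    then x100 to t/km2.  ``bgb_decay_weight`` is the committed fraction of
    belowground carbon within the accounting horizon; ``soc_weight``
    optionally discounts the soil pool.
    """
    pools.validate()
    if not 0 <= bgb_decay_weight <= 1:
        raise ValueError("bgb_decay_weight must be in [0, 1]")
    if not 0 <= soc_weight <= 1:
        raise ValueError("soc_weight must be in [0, 1]")
    c_agb = CARBON_TO_CO2E * BIOMASS_TO_CARBON * pools.agb_biomass * MG_HA_TO_T_KM2
    c_bgb = (
        CARBON_TO_CO2E * BIOMASS_TO_CARBON * bgb_decay_weight * pools.bgb_biomass
        * MG_HA_TO_T_KM2
    )
    c_soc = CARBON_TO_CO2E * soc_weight * pools.soc_carbon * MG_HA_TO_T_KM2
    rel_u = combine_uncertainties(
        [c_agb, c_bgb, c_soc], [pools.agb_rel_u, pools.bgb_rel_u, pools.soc_rel_u]
    )
    return CarbonEstimate(
        co2e_density_t_km2=c_agb + c_bgb + c_soc,
        relative_uncertainty=rel_u,
        decay_weight_applied=bgb_decay_weight,
        agb_contribution=c_agb,
        bgb_contribution=c_bgb,
        soc_contribution=c_soc,
    )


# ---------------------------------------------------------------------------
# table-level driver used by the pipeline


def carbon_estimates_table(
    carbon_sources: pd.DataFrame,
    mask_variants: list[str] | tuple[str, ...],
    agb_sources: list[str] | tuple[str, ...],
    bgb_sources: list[str] | tuple[str, ...],
    soc_sources: list[str] | tuple[str, ...],
    bgb_decay_horizon_years: float = 10.0,
    soc_weight: float = 1.0,
) -> pd.DataFrame:
    """Carbon estimate for every (jurisdiction, mask, AGB, BGB, SOC) cell.

    ``carbon_sources`` is the long observation table written by the
    synthetic-data stage.  Ratio-type BGB sources are resolved against the
    cell's AGB source; a ratio pool's uncertainty combines the AGB source
    uncertainty with the ratio's own (in quadrature) since the derived
    density inherits both errors.
    """
    decay_w = min(1.0, bgb_decay_horizon_years / 10.0)
    lut: dict[tuple[str, str, str], tuple[float, float, str]] = {}
    for row in carbon_sources.itertuples(index=False):
        lut[(row.jurisdiction_id, row.mask_variant, row.source)] = (
            float(row.value),
            default_uncertainty(row.rel_uncertainty),
            row.kind,
        )
    jids = carbon_sources["jurisdiction_id"].unique()
    rows = []
    for jid in jids:
        for mask in mask_variants:
            for agb_src in agb_sources:
                agb, u_agb, _ = lut[(jid, mask, agb_src)]
                for bgb_src in bgb_sources:
                    val, u_b, kind = lut[(jid, mask, bgb_src)]
                    if kind == "ratio":
                        bgb = bgb_from_ratio(agb, val)
                        u_bgb = float(np.sqrt(u_agb**2 + u_b**2))
                    else:
                        bgb, u_bgb = val, u_b
                    for soc_src in soc_sources:
                        soc, u_soc, _ = lut[(jid, mask, soc_src)]
                        est = pools_to_co2e(
                            CarbonPools(agb, bgb, soc, u_agb, u_bgb, u_soc),
                            bgb_decay_weight=decay_w,
                            soc_weight=soc_weight,
                        )
                        rows.append(
                            (
                                jid, mask, agb_src, bgb_src, soc_src,
                                est.co2e_density_t_km2,
                                est.relative_uncertainty,
                                u_agb, u_bgb,
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "jurisdiction_id", "mask_variant", "agb_source", "bgb_source",
            "soc_source", "co2e_per_km2", "carbon_rel_u", "agb_rel_u",
            "bgb_rel_u",
        ],
    )
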