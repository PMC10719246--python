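"""Shared fixtures: controlled generator configurations and hand-built panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from baseline_ensemble.config import (
    DEFAULT_VARIANT_SPANS,
    DRIVER_NAMES,
    GeneratorConfig,
)
from baseline_ensemble.synthetic_data import JurisdictionPanel


def _gen_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_jurisdictions=20,
        seed=0,
        subdivision_threshold_km2=1e12,  # no subnational splitting unless asked
        forest_area_sigma=0.0,
    )
    base.update(overrides)
    cfg = GeneratorConfig(**base)
    cfg.validate()
    return cfg


def _noise_free(**overrides) -> GeneratorConfig:
    quiet = dict(
        ar1_coefficient=0.0,
        process_noise_sd=0.0,
        observation_noise_cv={v: 0.0 for v in DEFAULT_VARIANT_SPANS},
        dataset_bias_factors={v: 1.0 for v in DEFAULT_VARIANT_SPANS},
    )
    quiet.update(overrides)
    return _gen_config(**quiet)


@pytest.fixture
def gen_config():
    """Factory for generator configs with test-friendly defaults."""
    return _gen_config


@pytest.fixture
def noise_free_config():
    """Factory for fully deterministic (noise-free, unbiased) configs."""
    return _noise_free


@pytest.fixture
def build_panel():
    """Hand-build a panel from explicit deforestation series.

    ``series_by_variant`` maps variant name -> (first_year, list of annual
    losses); the forest stock is derived by subtraction from ``forest0``.
    """

    def _build(
        jid: str = "X0",
        series_by_variant: dict | None = None,
        forest0: float = 5000.0,
        land_area: float = 20000.0,
        region: str = "Asia",
        admin_level: str = "national",
        parent_id: str | None = None,
        children_ids: tuple[str, ...] = (),
        drivers: pd.DataFrame | None = None,
    ) -> JurisdictionPanel:
        if series_by_variant is None:
            series_by_variant = {"modis": (2001, [10.0] * 20)}
        forest_by_variant, defor_by_variant = {}, {}
        for variant, (y0, losses) in series_by_variant.items():
            years = np.arange(y0, y0 + len(losses))
            defor = pd.Series(np.asarray(losses, dtype=float), index=years)
            forest = pd.Series(forest0 - defor.cumsum(), index=years)
            forest_by_variant[variant] = forest
            defor_by_variant[variant] = defor
        if drivers is None:
            all_years = sorted({y for v in forest_by_variant.values() for y in v.index})
            drivers = pd.DataFrame(
                0.0, index=all_years, columns=list(DRIVER_NAMES)
            )
        return JurisdictionPanel(
            jurisdiction_id=jid,
            admin_level=admin_level,
            region=region,
            land_area_km2=land_area,
            forest_area0_km2=forest0,
            forest_by_variant=forest_by_variant,
            defor_by_variant=defor_by_variant,
            drivers_by_year=drivers,
            parent_id=parent_id,
            children_ids=children_ids,
        )

    return _build
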