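"""End-to-end pipeline: terrain -> services -> sensitivity -> priorities."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import carbon as carbon_mod
from . import habitat
from . import prioritize as prioritize_mod
from . import sediment as sediment_mod
from . import sensitivity as sens_mod
from . import terrain as terrain_mod
from .grid import RasterGrid
from .synth import Landscape
from .tables import POOL_COLUMNS

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the full run produces, keyed the way the stages name it."""

    terrain: terrain_mod.TerrainProducts
    quality: RasterGrid
    degradation: RasterGrid
    threat_layers: list
    beta: RasterGrid
    carbon_stock: RasterGrid
    lulc_edged: RasterGrid
    usle: sediment_mod.USLEFactors
    soil_loss: RasterGrid
    retention: RasterGrid
    export: RasterGrid
    sensitivity: pd.DataFrame
    bundle: prioritize_mod.ServiceBundle
    correlations: pd.DataFrame
    bundling: pd.DataFrame
    priority: prioritize_mod.PriorityResult
    extras: dict = field(default_factory=dict)


def run_pipeline(
    land: Landscape,
    n_sensitivity: int = sens_mod.DEFAULT_N_SAMPLES,
    n_boot: int = sens_mod.DEFAULT_N_BOOT,
    seed: int = 0,
    window_radius: float = terrain_mod.DEFAULT_WINDOW_RADIUS_M,
    min_area_km2: float = terrain_mod.DEFAULT_MIN_AREA_KM2,
) -> PipelineResult:
    """Run every stage on one landscape bundle."""
    table = land.lulc_table
    log.info("terrain stage")
    tp = terrain_mod.derive_terrain(
        land.dem, window_radius=window_radius, min_area_km2=min_area_km2
    )
    log.info("habitat stage")
    quality, degradation, layers, beta = habitat.run_habitat_model(
        land.lulc, tp.cost_surface, land.protected, table
    )
    log.info("carbon stage")
    stock, edged = carbon_mod.run_carbon_model(land.lulc, table)
    log.info("sediment stage")
    usle = sediment_mod.build_usle_factors(
        land.erosivity, land.soil, land.soil_k_table, land.lulc, table,
        land.dem, tp.flow_acc,
    )
    a = sediment_mod.soil_loss(usle)
    retention, export, _ = sediment_mod.sediment_retention(usle, tp.flow_dir)

    log.info("sensitivity stage")
    codes = {int(r.code): str(r["name"]) for _, r in table.frame.iterrows()}
    impacts = {codes.get(t.class_code, str(t.class_code)): t.impact for t in layers}
    pool_grids = {
        col.upper(): edged.like(table.column_for(
            _safe_codes(edged, table), col))
        for col in POOL_COLUMNS
    }
    sets = sens_mod.build_predictor_sets(
        quality, impacts, beta, stock, pool_grids, retention, usle.grids()
    )
    sens = sens_mod.run_sensitivity(sets, n=n_sensitivity, n_boot=n_boot, seed=seed)

    log.info("prioritization stage")
    bundle = prioritize_mod.make_bundle(quality, stock, retention)
    corr = prioritize_mod.pearson_matrix(bundle)
    curves = prioritize_mod.bundling_overlap(bundle)
    priority = prioritize_mod.prioritize_areas(bundle, land.protected)
    return PipelineResult(
        tp, quality, degradation, layers, beta, stock, edged, usle, a,
        retention, export, sens, bundle, corr, curves, priority,
        extras={"soil_loss": a},
    )


def _safe_codes(lulc: RasterGrid, table) -> "object":
    import numpy as np

    return np.where(lulc.valid_mask, lulc.values, table.codes[0])
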