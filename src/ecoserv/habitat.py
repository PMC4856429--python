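"""Habitat quality: threat impacts, accessibility, degradation and quality.

The model scores each habitat cell by its exposure to anthropogenic threat
classes (pasture, urban, mining, ...).  A threat's impact decays
exponentially with the relief-aware cost distance ``d_c`` from its nearest
source cell,

    i_r(x) = exp(-(2.99 / d_max_r) * d_c(x)),

so that impact falls to ~5% at the class's maximum influence distance
``d_max`` (2.99 = -ln 0.05).  Impacts are combined into a total degradation
with weights normalized to sum to one and attenuated by an accessibility
factor beta (default 0.5 inside strictly protected areas, 1 elsewhere):

    D(x) = sum_r (w_r / sum w) * i_r(x) * beta(x),

and habitat quality on habitat cells follows the half-saturation form

    Q(x) = 1 - D / (D + k_half),      k_half = 0.5 by default.

Non-habitat cells have Q = 0.  All habitat classes are treated as equally
sensitive to every threat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid, require_aligned
from .tables import LULCTable
from .terrain import cost_distance

log = logging.getLogger(__name__)

#: Exponential decay constant: impact reaches 5% at d_max (= -ln 0.05).
DECAY_CONSTANT = 2.99

DEFAULT_STRICT_FACTOR = 0.5
DEFAULT_K_HALF = 0.5

#: Protected-area raster labels.
PA_NONE, PA_STRICT, PA_SUSTAINABLE = 0, 1, 2


@dataclass
class ThreatLayer:
    """Cost distance and impact surface for one threat class."""

    class_code: int
    d_max: float
    weight: float
    dc: RasterGrid
    impact: RasterGrid


def threat_impact(dc: RasterGrid, d_max: float, decay: float = DECAY_CONSTANT) -> RasterGrid:
    """Exponential distance-decay impact ``exp(-(decay/d_max) * d_c)``."""
    if d_max <= 0:
        raise ValueError(f"d_max must be positive, got {d_max}")
    d = dc.filled(np.nan)
    with np.errstate(invalid="ignore"):
        i = np.exp(-(decay / d_max) * d)
    i = np.nan_to_num(i, nan=0.0)  # unreachable cells (inf dc) -> zero impact
    return dc.like(i)


def accessibility_raster(
    protected: RasterGrid,
    strict_factor: float = DEFAULT_STRICT_FACTOR,
    excluded_labels: tuple[int, ...] = (),
) -> RasterGrid:
    """Accessibility factor beta: ``strict_factor`` inside strictly protected
    areas, 1 elsewhere (sustainable-use areas get no reduction).

    ``excluded_labels`` lists additional raster labels (e.g. a reserve too
    recent to be managed) that are treated as unprotected.
    """
    if not 0 < strict_factor <= 1:
        raise ValueError(f"strict_factor must lie in (0, 1], got {strict_factor}")
    labels = protected.values
    known = {PA_NONE, PA_STRICT, PA_SUSTAINABLE, *excluded_labels}
    present = set(np.unique(labels[protected.valid_mask]).astype(int))
    unknown = present - known
    if unknown:
        raise ValueError(f"unknown protected-area labels: {sorted(unknown)}")
    beta = np.ones(protected.shape, dtype=float)
    strict = (labels == PA_STRICT)
    for lab in excluded_labels:
        strict &= labels != lab
    beta[strict] = strict_factor
    return protected.like(beta)


def build_threat_layers(
    lulc: RasterGrid, cost: RasterGrid, table: LULCTable, decay: float = DECAY_CONSTANT
) -> list[ThreatLayer]:
    """Cost distance + impact for every threat class present in the table.

    Each threat class uses its own source mask (cells of that class) over the
    shared cost surface; classes absent from the map are skipped with a
    warning (their impact would be undefined without sources).
    """
    require_aligned(lulc, cost)
    layers: list[ThreatLayer] = []
    for _, row in table.threat_params().iterrows():
        mask = lulc.values == row.code
        if not mask.any():
            log.warning("threat class %s (%d) absent from LULC map; skipped", row["name"], row.code)
            continue
        dc = cost_distance(cost, mask)
        layers.append(
            ThreatLayer(int(row.code), float(row.d_max_m), float(row.weight), dc,
                        threat_impact(dc, float(row.d_max_m), decay))
        )
    if not layers:
        raise ValueError("no threat class from the table occurs on the LULC map")
    return layers


def total_degradation(threats: list[ThreatLayer], beta: RasterGrid) -> RasterGrid:
    """Weight-normalized, accessibility-attenuated total degradation D."""
    if not threats:
        raise ValueError("total_degradation requires at least one threat layer")
    w_sum = sum(t.weight for t in threats)
    if w_sum <= 0:
        raise ValueError("threat weights must not all be zero")
    require_aligned(*[t.impact for t in threats], beta)
    d = np.zeros(beta.shape, dtype=float)
    for t in threats:
        d += (t.weight / w_sum) * t.impact.filled(0.0)
    d *= beta.filled(1.0)
    bad = ~beta.valid_mask
    for t in threats:
        bad |= ~t.impact.valid_mask
    return beta.like(d, nodata_mask=bad)


def habitat_quality(
    degradation: RasterGrid,
    lulc: RasterGrid,
    table: LULCTable,
    k_half: float = DEFAULT_K_HALF,
) -> RasterGrid:
    """Half-saturation habitat quality; zero on non-habitat cells."""
    if k_half <= 0:
        raise ValueError(f"k_half must be positive, got {k_half}")
    require_aligned(degradation, lulc)
    d = degradation.filled(0.0)
    q = 1.0 - d / (d + k_half)
    is_hab = table.column_for(np.where(lulc.valid_mask, lulc.values, table.codes[0]), "is_habitat")
    q = np.where(is_hab > 0, q, 0.0)
    bad = ~(degradation.valid_mask & lulc.valid_mask)
    return degradation.like(q, nodata_mask=bad)


def run_habitat_model(
    lulc: RasterGrid,
    cost: RasterGrid,
    protected: RasterGrid,
    table: LULCTable,
    strict_factor: float = DEFAULT_STRICT_FACTOR,
    k_half: float = DEFAULT_K_HALF,
    decay: float = DECAY_CONSTANT,
) -> tuple[RasterGrid, RasterGrid, list[ThreatLayer], RasterGrid]:
    """Full habitat stage: returns (quality, degradation, threat layers, beta)."""
    layers = build_threat_layers(lulc, cost, table, decay)
    beta = accessibility_raster(protected, strict_factor)
    d = total_degradation(layers, beta)
    q = habitat_quality(d, lulc, table, k_half)
    return q, d, layers, beta
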