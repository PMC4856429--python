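"""Service rescaling, correlation, bundling and priority-area ranking.

The three service maps (habitat quality, carbon stock, sediment retention)
live on different scales, so each is rescaled to 0–100 by its own maximum
(``Z = X / X_max * 100``), with a log10(1+x) transform applied first to
sediment retention only, whose raw range spans orders of magnitude.

Bundling measures, for a ladder of thresholds, the area where all three (and
each pair of) rescaled maps exceed the threshold.  Priority areas are the
cells in the top 20% of at least two services; each such cell is then ranked
by a functional-connectivity proxy — the number of other priority cells
whose centers lie within a 250-m radius (an ocelot-scale movement distance)
— yielding a priority gradient.  Finally the gradient is summarized against
the protected-area raster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RasterGrid, joint_valid_mask, require_aligned

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)
DEFAULT_TOP_FRACTION = 0.20
DEFAULT_RADIUS_M = 250.0
DEFAULT_MIN_COUNT = 2


@dataclass
class ServiceBundle:
    """Aligned service maps plus their 0–100 rescaled versions."""

    quality: RasterGrid
    carbon: RasterGrid
    sediment: RasterGrid
    quality_z: RasterGrid
    carbon_z: RasterGrid
    sediment_z: RasterGrid

    @property
    def rescaled(self) -> dict[str, RasterGrid]:
        return {"habitat_quality": self.quality_z, "carbon": self.carbon_z,
                "sediment": self.sediment_z}


@dataclass
class PriorityResult:
    overlap_mask: RasterGrid
    aggregation_index: RasterGrid
    pa_stats: dict[str, float]


def rescale_0_100(grid: RasterGrid, log_first: bool = False) -> RasterGrid:
    """Rescale by the map maximum to 0–100; optional log10(1+x) first.

    The log form keeps zero-valued cells defined and is used only for
    sediment retention, whose amplitude is otherwise too high.
    """
    x = grid.filled(np.nan)
    if log_first:
        if (x[grid.valid_mask] < 0).any():
            raise ValueError("log rescale requires nonnegative values")
        x = np.log10(1.0 + x)
    xmax = np.nanmax(x)
    if not xmax > 0:
        raise ValueError("rescale needs at least one positive valid cell")
    return grid.like(np.nan_to_num(x / xmax * 100.0))


def make_bundle(
    quality: RasterGrid, carbon: RasterGrid, sediment: RasterGrid,
    log_sediment: bool = True,
) -> ServiceBundle:
    require_aligned(quality, carbon, sediment)
    return ServiceBundle(
        quality, carbon, sediment,
        rescale_0_100(quality), rescale_0_100(carbon),
        rescale_0_100(sediment, log_first=log_sediment),
    )


def pearson_matrix(bundle: ServiceBundle) -> pd.DataFrame:
    """Pairwise Pearson correlations over jointly valid cells (diagonal 1)."""
    maps = {"habitat_quality": bundle.quality, "carbon": bundle.carbon,
            "sediment": bundle.sediment}
    mask = joint_valid_mask(*maps.values())
    if mask.sum() < 2:
        raise ValueError("need at least two jointly valid cells")
    names = list(maps)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = maps[a].values[mask], maps[b].values[mask]
            if va.std() == 0 or vb.std() == 0:
                log.warning("constant map in correlation (%s vs %s); reported as NaN", a, b)
                r = np.nan
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def bundling_overlap(
    bundle: ServiceBundle, thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Overlap area (km²) above each threshold, for all three services and
    for each pair; monotone nonincreasing in the threshold."""
    z = bundle.rescaled
    mask = joint_valid_mask(*z.values())
    cell_km2 = bundle.quality.cell_area_km2
    names = list(z)
    rows = []
    for t in thresholds:
        above = {k: (g.values >= t) & mask for k, g in z.items()}
        row = {"threshold": t}
        row["all_three_km2"] = float(np.logical_and.reduce(list(above.values())).sum()) * cell_km2
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                row[f"{a}&{b}_km2"] = float((above[a] & above[b]).sum()) * cell_km2
        rows.append(row)
    return pd.DataFrame(rows)


def top_quantile_mask(grid: RasterGrid, fraction: float = DEFAULT_TOP_FRACTION) -> RasterGrid:
    """Boolean mask of the ``ceil(fraction * n_valid)`` highest-scoring cells.

    The count is exact for any tie structure: ties at the threshold are
    admitted in row-major order.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    valid = grid.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("grid has no valid cells")
    k = math.ceil(fraction * n_valid)
    flat_idx = np.flatnonzero(valid.ravel())
    vals = grid.values.ravel()[flat_idx].astype(float)
    order = np.lexsort((flat_idx, -vals))
    out = np.zeros(grid.shape, dtype=np.int64).ravel()
    out[flat_idx[order[:k]]] = 1
    return grid.like(out.reshape(grid.shape))


def multi_service_overlap(
    masks: list[RasterGrid], min_count: int = DEFAULT_MIN_COUNT
) -> RasterGrid:
    """Cells selected by at least ``min_count`` of the given masks."""
    require_aligned(*masks)
    count = np.zeros(masks[0].shape, dtype=np.int64)
    bad = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        count += m.values.astype(bool)
        bad |= ~m.valid_mask
    return masks[0].like((count >= min_count).astype(np.int64), nodata_mask=bad)


def _disk_kernel(radius_m: float, cell_size: float) -> np.ndarray:
    r = int(radius_m // cell_size)
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    k = ((di**2 + dj**2) * cell_size**2 <= radius_m**2).astype(float)
    k[r, r] = 0.0  # self excluded
    return k


def aggregation_index(
    mask: RasterGrid, radius: float = DEFAULT_RADIUS_M, include_self: bool = False
) -> RasterGrid:
    """Per-cell count of other selected cells within ``radius`` meters.

    This is the focal connectivity score that turns the overlap mask into a
    priority gradient; zero outside the mask.  Symmetric by construction
    (cell a counts b iff b counts a).
    """
    if radius < mask.cell_size:
        raise ValueError(f"radius {radius} m is below one cell ({mask.cell_size} m)")
    from scipy import ndimage

    m = mask.values.astype(bool) & mask.valid_mask
    kernel = _disk_kernel(radius, mask.cell_size)
    if include_self:
        kernel[kernel.shape[0] // 2, kernel.shape[1] // 2] = 1.0
    counts = ndimage.correlate(m.astype(float), kernel, mode="constant", cval=0.0)
    out = np.where(m, np.rint(counts), 0.0).astype(np.int64)
    return mask.like(out, nodata_mask=~mask.valid_mask)


def protected_overlap_stats(priority: RasterGrid, protected: RasterGrid) -> dict[str, float]:
    """Fraction of priority cells per protection category (sums to 1)."""
    require_aligned(priority, protected)
    sel = priority.values.astype(bool) & priority.valid_mask & protected.valid_mask
    n = int(sel.sum())
    if n == 0:
        return {"strict": 0.0, "sustainable": 0.0, "unprotected": 0.0}
    labels = protected.values[sel]
    return {
        "strict": float((labels == 1).sum()) / n,
        "sustainable": float((labels == 2).sum()) / n,
        "unprotected": float((labels == 0).sum()) / n,
    }


def prioritize_areas(
    bundle: ServiceBundle,
    protected: RasterGrid,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    min_count: int = DEFAULT_MIN_COUNT,
    radius: float = DEFAULT_RADIUS_M,
) -> PriorityResult:
    """Top-quantile overlap -> connectivity gradient -> protection summary."""
    masks = [top_quantile_mask(g, top_fraction) for g in bundle.rescaled.values()]
    overlap = multi_service_overlap(masks, min_count)
    agg = aggregation_index(overlap, radius)
    stats = protected_overlap_stats(overlap, protected)
    return PriorityResult(overlap, agg, stats)
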