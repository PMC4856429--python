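"""Synthetic landscapes with the structure the service models assume.

Real inputs for the study system (a rugged tropical mining province) are
proprietary, so every downstream stage is exercised on generated rasters:

* a DEM that sums ridge crests and a low-pass random field, rescaled to the
  region's 586–2087 m relief;
* an integer LULC mosaic grown from Poisson-seeded nuclei under exact class
  quotas, with habitat patches clustered, threats interspersed, roads drawn
  as one-cell polylines between urban nuclei, high cells biased toward
  rupestrian grassland and valleys toward urban/pasture/water;
* elevation-banded soil codes, a coarse-block (900 m) erosivity field, and
  compact protected-area polygons of two categories.

Everything is deterministic under ``(spec, seed)``, and the generated bundle
is mutually aligned.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import RasterGrid, align_check
from .tables import LULCTable, default_lulc_table, default_soil_k_table

#: Class proportions emulating the study region (forest merged across
#: interior and edge; the carbon stage re-derives the split).
DEFAULT_LULC_PROPORTIONS: dict[int, float] = {
    1: 0.4447,   # forest
    2: 0.1483,   # cerrado
    3: 0.0960,   # rupestrian grassland
    4: 0.0074,   # water
    5: 0.1377,   # pasture
    6: 0.0673,   # urban
    7: 0.0488,   # eucalyptus
    8: 0.0292,   # mining
    9: 0.0185,   # roads
    10: 0.0021,  # agriculture
}

ROADS_CODE = 9
URBAN_CODE = 6

#: (target elevation percentile, penalty strength) per class; classes not
#: listed are elevation-indifferent.
_ELEVATION_PREFS: dict[int, tuple[float, float]] = {
    1: (0.55, 0.6),   # forest: mid slopes
    2: (0.50, 0.3),   # cerrado
    3: (0.92, 3.0),   # rupestrian grassland: ridge tops
    4: (0.03, 4.0),   # water: valley bottoms
    5: (0.25, 1.5),   # pasture: low ground
    6: (0.12, 2.0),   # urban: valleys
    7: (0.35, 0.8),   # eucalyptus
    8: (0.80, 1.0),   # mining: upper slopes (ore bodies follow the ridges)
    10: (0.20, 1.5),  # agriculture
}


@dataclass
class LandscapeSpec:
    """Parameters of one synthetic landscape."""

    n_rows: int = 250
    n_cols: int = 250
    cell_size: float = 30.0
    seed: int = 0
    elevation_range: tuple[float, float] = (586.0, 2087.0)
    n_ridges: int = 4
    lulc_proportions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LULC_PROPORTIONS)
    )
    n_protected: tuple[int, int] = (2, 2)  # (strict, sustainable-use) polygons
    noise_amplitude: float = 1.0
    erosivity_range: tuple[float, float] = (5000.0, 12000.0)
    erosivity_block_m: float = 900.0
    n_soil_types: int = 4
    mean_patch_cells: int = 1200

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.elevation_range[0] >= self.elevation_range[1]:
            raise ValueError("elevation range must be increasing")
        total = sum(self.lulc_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"lulc_proportions must sum to 1, got {total}")


@dataclass
class Landscape:
    """Aligned raster bundle plus the default parameter tables."""

    dem: RasterGrid
    lulc: RasterGrid
    soil: RasterGrid
    erosivity: RasterGrid
    protected: RasterGrid
    lulc_table: LULCTable
    soil_k_table: "object"

    def grids(self) -> list[RasterGrid]:
        return [self.dem, self.lulc, self.soil, self.erosivity, self.protected]


# ---------------------------------------------------------------------------
# DEM
# ---------------------------------------------------------------------------

def generate_dem(spec: LandscapeSpec) -> RasterGrid:
    """Ridged, spatially correlated surface rescaled to the elevation range."""
    rng = np.random.default_rng(spec.seed)
    nr, nc = spec.n_rows, spec.n_cols
    ii, jj = np.mgrid[0:nr, 0:nc].astype(float)
    z = np.zeros((nr, nc))
    diag = math.hypot(nr, nc)
    for _ in range(spec.n_ridges):
        # a ridge is a Gaussian crest around a random line through the grid
        ci, cj = rng.uniform(0.15, 0.85) * nr, rng.uniform(0.15, 0.85) * nc
        ang = rng.uniform(0, math.pi)
        n_i, n_j = math.cos(ang), math.sin(ang)  # unit normal to the crest line
        dist = np.abs((ii - ci) * n_i + (jj - cj) * n_j)
        width = rng.uniform(0.05, 0.12) * diag
        z += rng.uniform(0.6, 1.0) * np.exp(-((dist / width) ** 2))
    if spec.noise_amplitude > 0:
        noise = rng.standard_normal((nr, nc))
        smooth = ndimage.gaussian_filter(noise, sigma=max(2.0, diag / 40.0))
        span = smooth.max() - smooth.min()
        if span > 0:
            z += spec.noise_amplitude * 0.6 * (smooth - smooth.min()) / span
    lo, hi = spec.elevation_range
    span = z.max() - z.min()
    if span == 0:
        z = np.full((nr, nc), (lo + hi) / 2.0)
    else:
        z = lo + (z - z.min()) / span * (hi - lo)
    return RasterGrid(z, spec.cell_size, (0.0, nr * spec.cell_size))


# ---------------------------------------------------------------------------
# LULC mosaic
# ---------------------------------------------------------------------------

def _bresenham(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    cells = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr, sc = (1 if r1 > r0 else -1), (1 if c1 > c0 else -1)
    err = dr - dc
    r, c = r0, c0
    while True:
        cells.append((r, c))
        if (r, c) == (r1, c1):
            break
        e2 = 2 * err
        if e2 > -dc:
            err -= dc
            r += sr
        if e2 < dr:
            err += dr
            c += sc
    return cells


def generate_lulc(dem: RasterGrid, spec: LandscapeSpec) -> RasterGrid:
    """Integer LULC mosaic under exact class quotas.

    Non-road classes grow by capacity-constrained multi-source region growing
    on a score field (elevation-preference penalty plus smooth noise), which
    yields clustered habitat patches and interspersed threats; roads are
    polylines connecting the urban nuclei, drawn first.  Empirical class
    fractions land within a fraction of a percentage point of the request.
    """
    total = sum(spec.lulc_proportions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"lulc_proportions must sum to 1, got {total}")
    rng = np.random.default_rng(spec.seed + 1)
    nr, nc = dem.shape
    n_cells = nr * nc
    elev_pct = dem.values.ravel().argsort().argsort().reshape(nr, nc) / max(n_cells - 1, 1)
    noise = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), sigma=2.0)
    span = noise.max() - noise.min()
    noise = (noise - noise.min()) / span if span > 0 else noise * 0.0

    classes = [c for c in spec.lulc_proportions if spec.lulc_proportions[c] > 0]
    if len(classes) == 1:
        return dem.like(np.full((nr, nc), classes[0], dtype=np.int64))

    # per-class static affinity score (lower = better)
    score = {}
    for c in classes:
        target, strength = _ELEVATION_PREFS.get(c, (0.5, 0.0))
        score[c] = strength * np.abs(elev_pct - target) + 0.6 * noise

    lulc = np.zeros((nr, nc), dtype=np.int64)

    # seed nuclei (Poisson-like: uniform random cells, biased by affinity)
    def place_seeds(c: int, k: int) -> list[tuple[int, int]]:
        cand = rng.integers(0, n_cells, size=max(20 * k, 50))
        sc = score[c].ravel()[cand]
        order = np.argsort(sc, kind="stable")
        out, seen = [], set()
        for idx in cand[order]:
            rc = (int(idx // nc), int(idx % nc))
            if rc not in seen:
                seen.add(rc)
                out.append(rc)
            if len(out) == k:
                break
        return out

    road_target = spec.lulc_proportions.get(ROADS_CODE, 0.0)
    urban_prop = spec.lulc_proportions.get(URBAN_CODE, 0.0)
    n_urban_seeds = max(2, round(urban_prop * n_cells / spec.mean_patch_cells)) if urban_prop else 0
    urban_seeds = place_seeds(URBAN_CODE, n_urban_seeds) if n_urban_seeds else []

    # roads: polylines between consecutive urban nuclei (plus a few random spurs)
    if road_target > 0 and len(urban_seeds) >= 2:
        road_quota = round(road_target * n_cells)
        pts = sorted(urban_seeds)
        pairs = list(zip(pts[:-1], pts[1:]))
        for n_seg, ((r0, c0), (r1, c1)) in enumerate(itertools.cycle(pairs)):
            for r, cidx in _bresenham(r0, c0, r1, c1):
                if lulc[r, cidx] == 0:
                    lulc[r, cidx] = ROADS_CODE
            if (lulc == ROADS_CODE).sum() >= road_quota or n_seg > 10_000:
                break
            # extend with a random spur so long grids still reach the quota
            rr = (int(rng.integers(0, nr)), int(rng.integers(0, nc)))
            pairs.append(((r1, c1), rr))
        road_cells = int((lulc == ROADS_CODE).sum())
    else:
        road_cells = 0

    grow_classes = [c for c in classes if c != ROADS_CODE]
    remaining = n_cells - road_cells
    prop_sum = sum(spec.lulc_proportions[c] for c in grow_classes)
    quota = {c: int(round(spec.lulc_proportions[c] / prop_sum * remaining)) for c in grow_classes}
    # fix rounding drift on the largest class
    drift = remaining - sum(quota.values())
    quota[max(grow_classes, key=lambda c: quota[c])] += drift

    counter = itertools.count()
    heap: list[tuple[float, int, int, int, int]] = []

    def push(c: int, r: int, cc: int) -> None:
        heapq.heappush(heap, (float(score[c][r, cc]), next(counter), c, r, cc))

    for c in grow_classes:
        if quota[c] <= 0:
            continue
        k = max(1, round(quota[c] / spec.mean_patch_cells))
        seeds = urban_seeds[: k] if c == URBAN_CODE and urban_seeds else place_seeds(c, k)
        for r, cc in seeds:
            push(c, r, cc)

    filled = {c: 0 for c in grow_classes}
    n_assigned = road_cells
    offsets = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))
    while n_assigned < n_cells:
        if not heap:
            # re-seed classes that still have quota on any unassigned cell
            free = np.argwhere(lulc == 0)
            if not len(free):
                break
            for c in grow_classes:
                if filled[c] < quota[c]:
                    sc = score[c][free[:, 0], free[:, 1]]
                    r, cc = free[int(np.argmin(sc))]
                    push(c, int(r), int(cc))
                    break
            else:
                break
            continue
        _, _, c, r, cc = heapq.heappop(heap)
        if lulc[r, cc] != 0 or filled[c] >= quota[c]:
            continue
        lulc[r, cc] = c
        filled[c] += 1
        n_assigned += 1
        for dr, dc in offsets:
            r2, c2 = r + dr, cc + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and lulc[r2, c2] == 0 and filled[c] < quota[c]:
                push(c, r2, c2)

    return dem.like(lulc)


# ---------------------------------------------------------------------------
# Ancillary rasters
# ---------------------------------------------------------------------------

def generate_ancillary(
    dem: RasterGrid, spec: LandscapeSpec
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Soil codes, erosivity, and protected-area labels aligned with the DEM."""
    rng = np.random.default_rng(spec.seed + 2)
    nr, nc = dem.shape

    # soil: elevation-banded integer codes 1..n (lowland latosols through
    # litholic ridge soils), lightly smoothed to keep bands contiguous
    n_soil = spec.n_soil_types
    ranks = dem.values.ravel().argsort().argsort().reshape(nr, nc) / max(nr * nc - 1, 1)
    soil = np.clip((ranks * n_soil).astype(np.int64) + 1, 1, n_soil)
    soil = ndimage.median_filter(soil, size=5)

    # erosivity: smooth coarse field replicated over 900-m blocks
    block = max(1, int(round(spec.erosivity_block_m / spec.cell_size)))
    cr, cc = -(-nr // block), -(-nc // block)
    coarse = ndimage.gaussian_filter(rng.standard_normal((cr, cc)), sigma=1.5)
    span = coarse.max() - coarse.min()
    lo, hi = spec.erosivity_range
    coarse = (lo + hi) / 2.0 if span == 0 else lo + (coarse - coarse.min()) / span * (hi - lo)
    erosivity = np.kron(np.atleast_2d(coarse), np.ones((block, block)))[:nr, :nc]

    # protected areas: compact rotated-ellipse polygons; strict (1) drawn
    # last so it wins where the two categories would overlap
    protected = np.zeros((nr, nc), dtype=np.int64)
    ii, jj = np.mgrid[0:nr, 0:nc].astype(float)
    for label, count in ((2, spec.n_protected[1]), (1, spec.n_protected[0])):
        for _ in range(count):
            ci, cj = rng.uniform(0.1, 0.9) * nr, rng.uniform(0.1, 0.9) * nc
            a = rng.uniform(0.04, 0.12) * min(nr, nc)
            b = rng.uniform(0.04, 0.12) * min(nr, nc)
            ang = rng.uniform(0, math.pi)
            u = (ii - ci) * math.cos(ang) + (jj - cj) * math.sin(ang)
            v = -(ii - ci) * math.sin(ang) + (jj - cj) * math.cos(ang)
            protected[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = label

    return dem.like(soil), dem.like(erosivity), dem.like(protected)


def generate_landscape(spec: LandscapeSpec) -> Landscape:
    """Full aligned bundle (DEM, LULC, soil, erosivity, protected + tables)."""
    dem = generate_dem(spec)
    lulc = generate_lulc(dem, spec)
    soil, erosivity, protected = generate_ancillary(dem, spec)
    bundle = Landscape(dem, lulc, soil, erosivity, protected,
                       default_lulc_table(), default_soil_k_table())
    assert align_check(bundle.grids())
    return bundle
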