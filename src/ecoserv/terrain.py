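"""Relief products: slope, slope-corrected distance, curvature barriers,
cost surfaces and cost distance, and D8 hydrology with sub-watershed labels.

The habitat-quality model propagates threats over the terrain rather than in
straight lines: per-cell traversal distance grows with slope
(``d_a = cell / cos(slope)``), and ridge crests — the cells in the top
fraction of maximum relief curvature — are recoded to a prohibitive barrier
cost so impacts do not cross them.  Cost distance from each threat class is
the least accumulated cost over 8-connected moves.

Hydrology is single-direction (D8): pits are filled by morphological
reconstruction, flats are resolved by a breadth-first sweep from their
spill cells, accumulation counts upstream cells, and sub-watersheds are the
drainage basins of terminal cells, greedily merged until each labeled basin
reaches a minimum area.
"""

from __future__ import annotations

import heapq
import logging
import math
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .grid import RasterGrid, require_aligned

log = logging.getLogger(__name__)

#: Neighbor offsets in fixed order: E, SE, S, SW, W, NW, N, NE.
D8_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))
_SQRT2 = math.sqrt(2.0)
D8_DISTANCES = tuple(_SQRT2 if dr and dc else 1.0 for dr, dc in D8_OFFSETS)

#: flow-direction sentinel codes
FLOW_OUTLET = -1   # drains off the grid (or into nodata)
FLOW_NODATA = -2

DEFAULT_SLOPE_CAP_DEG = 89.0
DEFAULT_BARRIER_VALUE = 300.0
DEFAULT_TOP_FRACTION = 0.20
DEFAULT_WINDOW_RADIUS_M = 500.0
DEFAULT_MIN_AREA_KM2 = 36.0


@dataclass
class TerrainProducts:
    """Bundle of all relief-derived rasters for one DEM."""

    slope_deg: RasterGrid
    d_a: RasterGrid
    curvature: RasterGrid
    mcr: RasterGrid
    cost_surface: RasterGrid
    flow_dir: RasterGrid
    flow_acc: RasterGrid
    watershed_id: RasterGrid


# ---------------------------------------------------------------------------
# Slope and slope-corrected distance
# ---------------------------------------------------------------------------

def compute_slope(dem: RasterGrid) -> RasterGrid:
    """Slope in degrees by Horn's 3x3 finite differences.

    Border cells use clamped (edge-replicated) neighborhoods, so a constant
    DEM is 0 everywhere and a uniform ramp keeps its interior slope at the
    border rows parallel to the gradient.
    """
    z = dem.filled(np.nan)
    # replace nodata by local neighborhood means so the stencil stays finite;
    # affected cells are re-blanked below
    if np.isnan(z).any():
        z = np.where(np.isnan(z), np.nanmean(z), z)
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)
    dzdx = ndimage.correlate(z, kx, mode="nearest") / (8.0 * dem.cell_size)
    dzdy = ndimage.correlate(z, ky, mode="nearest") / (8.0 * dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.like(slope)


def slope_corrected_distance(
    slope_deg: RasterGrid, cell_size: float | None = None, cap_deg: float = DEFAULT_SLOPE_CAP_DEG
) -> RasterGrid:
    """Per-cell traversal distance ``d_a = cell_size / cos(slope)`` in meters.

    On flat terrain this is exactly the cell size; it grows monotonically
    with slope.  Slopes at or above ``cap_deg`` are clamped to keep the
    cosine away from zero.
    """
    if cell_size is None:
        cell_size = slope_deg.cell_size
    s = slope_deg.filled(0.0)
    if (s[slope_deg.valid_mask] >= cap_deg).any():
        log.warning("slopes >= %.1f deg clamped in d_a computation", cap_deg)
    s = np.minimum(s, cap_deg)
    if (s < 0).any() or (s >= 90).any():
        raise ValueError("slope must lie in [0, 90) degrees")
    d_a = cell_size / np.cos(np.radians(s))
    return slope_deg.like(d_a)


# ---------------------------------------------------------------------------
# Maximum curvature and barrier raster
# ---------------------------------------------------------------------------

def _quadratic_fit_kernels(radius_cells: int, cell_size: float) -> dict[str, np.ndarray]:
    """Linear filters giving the quadratic-surface coefficients a, b, c of
    z = a*x^2 + b*y^2 + c*x*y + d*x + e*y + f, least-squares fitted over the
    circular window of the given radius (in cells)."""
    r = radius_cells
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    inside = di**2 + dj**2 <= r**2
    x = dj[inside] * cell_size
    y = -di[inside] * cell_size  # row axis points south
    M = np.column_stack([x**2, y**2, x * y, x, y, np.ones_like(x)])
    pinv = np.linalg.pinv(M)  # (6, n_pts)
    kernels = {}
    for row, name in zip(pinv[:3], ("a", "b", "c")):
        k = np.zeros_like(di, dtype=float)
        k[inside] = row
        kernels[name] = k
    return kernels


def max_curvature(dem: RasterGrid, window_radius: float = DEFAULT_WINDOW_RADIUS_M) -> RasterGrid:
    """Maximum principal curvature of a windowed quadratic surface fit.

    Every cell gets the larger eigenvalue of the negated Hessian of the
    bivariate quadratic least-squares fitted to all cells within
    ``window_radius`` meters, so convex-up crests score positive and bowls
    negative.  Units are 1/m (relative; only the ranking feeds the barrier).
    """
    if window_radius < dem.cell_size:
        raise ValueError(
            f"window_radius {window_radius} m is below one cell ({dem.cell_size} m)"
        )
    r = int(window_radius // dem.cell_size)
    if r < 1:
        raise ValueError("curvature window must span at least a 3x3 neighborhood")
    z = dem.filled(np.nan)
    if np.isnan(z).any():
        z = np.where(np.isnan(z), np.nanmean(z), z)
    k = _quadratic_fit_kernels(r, dem.cell_size)
    a = ndimage.correlate(z, k["a"], mode="nearest")
    b = ndimage.correlate(z, k["b"], mode="nearest")
    c = ndimage.correlate(z, k["c"], mode="nearest")
    # Hessian of the fit is [[2a, c], [c, 2b]]; crests convex up -> negate.
    # Report the principal curvature of larger magnitude (signed), so both
    # sharp crests (positive) and sharp troughs (negative) register.
    tr = -(2 * a + 2 * b)
    det = (2 * a) * (2 * b) - c**2
    disc = np.sqrt(np.maximum(tr**2 - 4 * det, 0.0))
    lam1 = (tr + disc) / 2.0
    lam2 = (tr - disc) / 2.0
    lam_max = np.where(np.abs(lam1) >= np.abs(lam2), lam1, lam2)
    return dem.like(lam_max)


def barrier_raster(
    curvature: RasterGrid,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    barrier_value: float = DEFAULT_BARRIER_VALUE,
) -> RasterGrid:
    """Recode the highest-curvature cells to a prohibitive barrier value.

    Exactly ``ceil(top_fraction * n_valid)`` cells receive ``barrier_value``;
    all other valid cells are 0.  Ties at the threshold are broken
    deterministically in row-major order.
    """
    if not 0 < top_fraction < 1:
        raise ValueError(f"top_fraction must lie in (0, 1), got {top_fraction}")
    valid = curvature.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("curvature raster has no valid cells")
    k = math.ceil(top_fraction * n_valid)
    flat_idx = np.flatnonzero(valid.ravel())
    vals = curvature.values.ravel()[flat_idx].astype(float)
    # sort by value descending, ties by row-major position ascending
    order = np.lexsort((flat_idx, -vals))
    chosen = flat_idx[order[:k]]
    out = np.zeros(curvature.shape, dtype=float).ravel()
    out[chosen] = barrier_value
    return curvature.like(out.reshape(curvature.shape))


def cost_surface(d_a: RasterGrid, mcr: RasterGrid) -> RasterGrid:
    """Element-wise sum of slope-corrected distance and the barrier raster."""
    require_aligned(d_a, mcr)
    out = d_a.filled(0.0) + mcr.filled(0.0)
    bad = ~(d_a.valid_mask & mcr.valid_mask)
    return d_a.like(out, nodata_mask=bad)


# ---------------------------------------------------------------------------
# Cost distance
# ---------------------------------------------------------------------------

def cost_distance(cost: RasterGrid, sources: RasterGrid | np.ndarray) -> RasterGrid:
    """Least accumulated cost (meters) from any source cell, 8-connected.

    A move between adjacent cells a and b costs ``(cost(a) + cost(b)) / 2``,
    times sqrt(2) for diagonal moves; the per-cell cost already carries the
    traversal distance in meters, so no extra cell-size factor applies.
    Source cells are 0.  Valid cells unreachable from any source are +inf.
    """
    src_mask = sources.values.astype(bool) if isinstance(sources, RasterGrid) else np.asarray(sources, dtype=bool)
    if isinstance(sources, RasterGrid):
        require_aligned(cost, sources)
    if src_mask.shape != cost.shape:
        raise ValueError("source mask shape does not match cost grid")
    valid = cost.valid_mask
    c = cost.filled(np.nan)
    if (c[valid] <= 0).any():
        raise ValueError("cost surface must be strictly positive on valid cells")
    src_mask = src_mask & valid
    if not src_mask.any():
        raise ValueError("cost_distance requires at least one valid source cell")

    nr, nc = cost.shape
    idx = np.arange(nr * nc).reshape(nr, nc)
    rows_list, cols_list, w_list = [], [], []
    # undirected graph: emit each edge once (E, SE, S, SW offsets)
    for (dr, dc), dist in zip(D8_OFFSETS[:4], D8_DISTANCES[:4]):
        if dr >= 0:
            a = (slice(0, nr - dr), slice(max(0, -dc), nc - max(0, dc)))
            b = (slice(dr, nr), slice(max(0, dc), nc - max(0, -dc)))
        va = valid[a] & valid[b]
        if not va.any():
            continue
        w = (c[a] + c[b]) / 2.0 * dist
        rows_list.append(idx[a][va])
        cols_list.append(idx[b][va])
        w_list.append(w[va])
    graph = sparse.csr_matrix(
        (np.concatenate(w_list), (np.concatenate(rows_list), np.concatenate(cols_list))),
        shape=(nr * nc, nr * nc),
    )
    src_idx = np.flatnonzero(src_mask.ravel())
    d = dijkstra(graph, directed=False, indices=src_idx, min_only=True)
    out = d.reshape(nr, nc)
    return cost.like(out, nodata_mask=~valid)


# ---------------------------------------------------------------------------
# D8 hydrology
# ---------------------------------------------------------------------------

def fill_pits(dem: RasterGrid) -> RasterGrid:
    """Raise interior depressions to their spill level.

    Morphological reconstruction by erosion with the DEM as mask and a seed
    that keeps the border (and cells next to nodata) at their true elevation;
    the result is the lowest surface >= DEM that drains to the border.
    """
    from skimage.morphology import reconstruction

    valid = dem.valid_mask
    z = dem.filled(0.0)
    lo = z[valid].min() if valid.any() else 0.0
    z = np.where(valid, z, lo - 1.0)
    seed = np.full_like(z, z.max() + 1.0)
    border = np.zeros_like(valid)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    anchor = border | ~valid
    seed[anchor] = z[anchor]
    filled = reconstruction(seed, z, method="erosion", footprint=np.ones((3, 3)))
    return dem.like(filled, nodata_mask=~valid)


def flow_direction(filled_dem: RasterGrid) -> RasterGrid:
    """D8 steepest-descent direction codes (indices into ``D8_OFFSETS``).

    Cells with no lower neighbor on the grid border (or next to nodata) are
    outlets (:data:`FLOW_OUTLET`); interior flats drain toward their spill
    cells via a breadth-first sweep.  Nodata cells get :data:`FLOW_NODATA`.
    """
    valid = filled_dem.valid_mask
    z = filled_dem.filled(np.nan)
    nr, nc = z.shape
    best_drop = np.full((nr, nc), 0.0)
    fdir = np.full((nr, nc), FLOW_NODATA, dtype=np.int8)
    fdir[valid] = -3  # unresolved
    cell = filled_dem.cell_size

    for code, ((dr, dc), dist) in enumerate(zip(D8_OFFSETS, D8_DISTANCES)):
        zn = np.full((nr, nc), np.nan)
        a_r = slice(max(0, -dr), nr - max(0, dr))
        a_c = slice(max(0, -dc), nc - max(0, dc))
        b_r = slice(max(0, dr), nr - max(0, -dr))
        b_c = slice(max(0, dc), nc - max(0, -dc))
        zn[a_r, a_c] = z[b_r, b_c]
        drop = (z - zn) / (dist * cell)
        better = valid & np.isfinite(drop) & (drop > best_drop)
        best_drop[better] = drop[better]
        fdir[better] = code

    # border / next-to-nodata cells with no lower neighbor drain off-grid
    unresolved = fdir == -3
    border = np.zeros((nr, nc), dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    near_nodata = ndimage.binary_dilation(~valid, structure=np.ones((3, 3))) & valid
    outlet = unresolved & (border | near_nodata)
    fdir[outlet] = FLOW_OUTLET
    unresolved &= ~outlet

    if unresolved.any():
        _resolve_flats(z, fdir, unresolved)
    if (fdir == -3).any():
        # isolated unresolved cells (should not happen after filling): outlets
        log.warning("%d cells could not be routed; marked as outlets", int((fdir == -3).sum()))
        fdir[fdir == -3] = FLOW_OUTLET
    return filled_dem.like(fdir.astype(np.int64), nodata_mask=~valid)


def _resolve_flats(z: np.ndarray, fdir: np.ndarray, flats: np.ndarray) -> None:
    """Point flat cells toward their nearest resolved equal-or-lower neighbor
    (breadth-first from the flat edges); mutates ``fdir`` in place."""
    nr, nc = z.shape
    queue: deque[tuple[int, int]] = deque()
    # seed: flat cells adjacent to an already-routed cell of equal or lower z
    seeds = np.zeros_like(flats)
    routed = (fdir >= 0) | (fdir == FLOW_OUTLET)
    for code, (dr, dc) in enumerate(D8_OFFSETS):
        zn = np.full((nr, nc), np.inf)
        rn = np.zeros((nr, nc), dtype=bool)
        a_r = slice(max(0, -dr), nr - max(0, dr))
        a_c = slice(max(0, -dc), nc - max(0, dc))
        b_r = slice(max(0, dr), nr - max(0, -dr))
        b_c = slice(max(0, dc), nc - max(0, -dc))
        zn[a_r, a_c] = z[b_r, b_c]
        rn[a_r, a_c] = routed[b_r, b_c]
        ok = flats & rn & (zn <= z) & ~seeds
        for i, j in zip(*np.nonzero(ok)):
            fdir[i, j] = code
            seeds[i, j] = True
    for i, j in zip(*np.nonzero(seeds)):
        queue.append((i, j))
    flats = flats & ~seeds
    while queue:
        i, j = queue.popleft()
        for code, (dr, dc) in enumerate(D8_OFFSETS):
            ni, nj = i - dr, j - dc  # neighbor that would flow INTO (i, j)
            if 0 <= ni < nr and 0 <= nj < nc and flats[ni, nj] and z[ni, nj] >= z[i, j]:
                flats[ni, nj] = False
                fdir[ni, nj] = code
                queue.append((ni, nj))


def flow_accumulation(flow_dir: RasterGrid) -> RasterGrid:
    """Number of upstream cells draining through each cell (self excluded)."""
    fdir = flow_dir.values.astype(np.int64)
    valid = flow_dir.valid_mask
    nr, nc = fdir.shape
    n = nr * nc
    flat_dir = fdir.ravel()
    down = np.full(n, -1, dtype=np.int64)
    cell_ids = np.flatnonzero(valid.ravel() & (flat_dir >= 0))
    drs = np.array([o[0] for o in D8_OFFSETS])
    dcs = np.array([o[1] for o in D8_OFFSETS])
    ri, ci = cell_ids // nc, cell_ids % nc
    d = flat_dir[cell_ids]
    down[cell_ids] = (ri + drs[d]) * nc + (ci + dcs[d])

    indeg = np.bincount(down[down >= 0], minlength=n)
    acc = np.zeros(n, dtype=np.int64)
    stack = list(np.flatnonzero(valid.ravel() & (indeg == 0)))
    while stack:
        u = stack.pop()
        v = down[u]
        if v < 0:
            continue
        acc[v] += acc[u] + 1
        indeg[v] -= 1
        if indeg[v] == 0:
            stack.append(v)
    return flow_dir.like(acc.reshape(nr, nc), nodata_mask=~valid)


def _basin_labels(flow_dir: RasterGrid) -> np.ndarray:
    """Label every valid cell by the terminal (outlet) cell it drains to,
    using pointer doubling over the downstream map.  Returns flat terminal
    indices, -1 on nodata."""
    fdir = flow_dir.values.astype(np.int64)
    valid = flow_dir.valid_mask
    nr, nc = fdir.shape
    n = nr * nc
    flat_dir = fdir.ravel()
    nxt = np.arange(n, dtype=np.int64)  # terminals (and nodata) point to self
    cell_ids = np.flatnonzero(valid.ravel() & (flat_dir >= 0))
    drs = np.array([o[0] for o in D8_OFFSETS])
    dcs = np.array([o[1] for o in D8_OFFSETS])
    ri, ci = cell_ids // nc, cell_ids % nc
    d = flat_dir[cell_ids]
    nxt[cell_ids] = (ri + drs[d]) * nc + (ci + dcs[d])
    for _ in range(64):
        new = nxt[nxt]
        if np.array_equal(new, nxt):
            break
        nxt = new
    nxt[~valid.ravel()] = -1
    return nxt


def label_watersheds(
    flow_dir: RasterGrid, min_area_km2: float = DEFAULT_MIN_AREA_KM2
) -> RasterGrid:
    """Sub-watershed labels (1..n), each basin at least ``min_area_km2``.

    Basins start as the drainage areas of terminal cells and are greedily
    merged — smallest first, into the adjacent basin sharing the longest
    boundary — until every label meets the minimum area.  If the whole grid
    is smaller than the minimum, a single watershed covers all valid cells.
    """
    valid = flow_dir.valid_mask
    nr, nc = flow_dir.shape
    terminals = _basin_labels(flow_dir)
    uniq, labels_flat = np.unique(terminals, return_inverse=True)
    labels = labels_flat.reshape(nr, nc).astype(np.int64)
    nodata_label = int(np.nonzero(uniq == -1)[0][0]) if (uniq == -1).any() else -1

    min_cells = math.ceil(min_area_km2 * 1e6 / flow_dir.cell_size**2)
    n_lab = len(uniq)
    areas = np.bincount(labels_flat, minlength=n_lab).astype(np.int64)
    if nodata_label >= 0:
        areas[nodata_label] = 0

    # adjacency counts between labels (8-connectivity)
    pair_counts: dict[tuple[int, int], int] = {}
    for dr, dc in D8_OFFSETS[:4]:
        a = labels[max(0, -dr) : nr - max(0, dr), max(0, -dc) : nc - max(0, dc)]
        b = labels[max(0, dr) : nr - max(0, -dr), max(0, dc) : nc - max(0, -dc)]
        m = (a != b)
        if nodata_label >= 0:
            m &= (a != nodata_label) & (b != nodata_label)
        pa, pb = a[m], b[m]
        lo, hi = np.minimum(pa, pb), np.maximum(pa, pb)
        pairs, counts = np.unique(np.stack([lo, hi], axis=1), axis=0, return_counts=True)
        for (x, y), cnt in zip(pairs, counts):
            key = (int(x), int(y))
            pair_counts[key] = pair_counts.get(key, 0) + int(cnt)

    parent = list(range(n_lab))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    neighbors: dict[int, dict[int, int]] = {i: {} for i in range(n_lab)}
    for (x, y), cnt in pair_counts.items():
        neighbors[x][y] = neighbors[x].get(y, 0) + cnt
        neighbors[y][x] = neighbors[y].get(x, 0) + cnt

    live = {i for i in range(n_lab) if i != nodata_label}
    heap = [(areas[i], i) for i in live]
    heapq.heapify(heap)
    while len(live) > 1:
        area, i = heapq.heappop(heap)
        if i not in live or find(i) != i or areas[i] != area:
            continue
        if area >= min_cells:
            break
        nbrs = {find(j): c for j, c in neighbors[i].items() if find(j) != i and find(j) in live}
        if not nbrs:
            break
        # merge into neighbor with longest shared boundary; ties by label id
        target = min(nbrs, key=lambda j: (-nbrs[j], j))
        parent[i] = target
        live.discard(i)
        areas[target] += areas[i]
        merged: dict[int, int] = {}
        for j, c in list(neighbors[i].items()) + list(neighbors[target].items()):
            rj = find(j)
            if rj != target and rj in live:
                merged[rj] = merged.get(rj, 0) + c
        neighbors[target] = merged
        for j, c in merged.items():
            neighbors[j][target] = c
        heapq.heappush(heap, (areas[target], target))

    roots = np.array([find(i) for i in range(n_lab)])
    final_ids = {r: k + 1 for k, r in enumerate(sorted({roots[i] for i in live}))}
    remap = np.zeros(n_lab, dtype=np.int64)
    for i in range(n_lab):
        if i != nodata_label and roots[i] in final_ids:
            remap[i] = final_ids[roots[i]]
    out = remap[labels_flat].reshape(nr, nc)
    return flow_dir.like(out, nodata_mask=~valid)


def d8_hydrology(
    dem: RasterGrid, min_area_km2: float = DEFAULT_MIN_AREA_KM2
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Pit-fill, route (D8), accumulate, and label sub-watersheds."""
    filled = fill_pits(dem)
    fdir = flow_direction(filled)
    acc = flow_accumulation(fdir)
    ws = label_watersheds(fdir, min_area_km2)
    return fdir, acc, ws


# ---------------------------------------------------------------------------
# Full terrain stage
# ---------------------------------------------------------------------------

def derive_terrain(
    dem: RasterGrid,
    window_radius: float = DEFAULT_WINDOW_RADIUS_M,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    barrier_value: float = DEFAULT_BARRIER_VALUE,
    min_area_km2: float = DEFAULT_MIN_AREA_KM2,
) -> TerrainProducts:
    """Compute every relief product the service models consume."""
    slope = compute_slope(dem)
    d_a = slope_corrected_distance(slope, dem.cell_size)
    curv = max_curvature(dem, window_radius)
    mcr = barrier_raster(curv, top_fraction, barrier_value)
    cost = cost_surface(d_a, mcr)
    fdir, acc, ws = d8_hydrology(dem, min_area_km2)
    return TerrainProducts(slope, d_a, curv, mcr, cost, fdir, acc, ws)
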