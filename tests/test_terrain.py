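"""Relief products: slope, d_a, curvature, barriers, cost distance, D8."""

import math

import numpy as np
import pytest

from ecoserv import RasterGrid
from ecoserv.terrain import (
    barrier_raster,
    compute_slope,
    cost_distance,
    cost_surface,
    d8_hydrology,
    fill_pits,
    flow_accumulation,
    flow_direction,
    max_curvature,
    slope_corrected_distance,
)


# ---------------------------------------------------------------------------
# slope and d_a
# ---------------------------------------------------------------------------

def test_flat_dem_has_zero_slope(flat_dem):
    slope = compute_slope(flat_dem)
    assert np.allclose(slope.values, 0.0)


def test_plane_slope_matches_analytic_gradient():
    # plane rising 30 m per 30-m cell eastward -> 45 degrees everywhere
    cols = np.arange(10) * 30.0
    dem = RasterGrid(np.tile(cols, (8, 1)), cell_size=30.0)
    slope = compute_slope(dem)
    assert np.allclose(slope.values[:, 1:-1], 45.0, atol=1e-9)


def test_slope_strictly_below_ninety():
    rng = np.random.default_rng(5)
    dem = RasterGrid(rng.uniform(0, 5000, size=(20, 20)), cell_size=30.0)
    assert compute_slope(dem).max() < 90.0


@pytest.mark.parametrize(
    "theta,expected",
    [(0.0, 30.0), (60.0, 60.0), (45.0, 30.0 * math.sqrt(2.0))],
)
def test_slope_corrected_distance_values(theta, expected):
    slope = RasterGrid(np.full((3, 3), theta), cell_size=30.0)
    d_a = slope_corrected_distance(slope, 30.0)
    assert d_a.values[1, 1] == pytest.approx(expected, rel=1e-6)


def test_d_a_monotone_in_slope_and_clamped():
    thetas = np.array([[0.0, 30.0, 60.0, 85.0, 89.5]])
    d_a = slope_corrected_distance(RasterGrid(thetas, cell_size=30.0), 30.0)
    vals = d_a.values[0]
    assert (np.diff(vals[:4]) > 0).all()
    cap = 30.0 / math.cos(math.radians(89.0))
    assert vals[4] == pytest.approx(cap)


# ---------------------------------------------------------------------------
# curvature and barriers
# ---------------------------------------------------------------------------

def test_planar_dem_zero_curvature():
    ii, jj = np.mgrid[0:20, 0:20].astype(float)
    dem = RasterGrid(3.0 * ii + 2.0 * jj, cell_size=30.0)
    curv = max_curvature(dem, window_radius=150.0)
    # interior cells only: border neighborhoods are edge-replicated
    assert np.allclose(curv.values[5:-5, 5:-5], 0.0, atol=1e-12)


def test_bowl_curvature_constant_interior():
    # z = (x - x0)^2: quadratic fit recovers the second derivative exactly,
    # so interior curvature has constant magnitude 2 (per m^2 scale)
    jj = np.arange(30, dtype=float)
    x = (jj - 15.0) * 30.0
    dem = RasterGrid(np.tile(x**2, (30, 1)) * 1e-4, cell_size=30.0)
    curv = max_curvature(dem, window_radius=150.0)
    interior = curv.values[10:-10, 10:-10]
    assert np.allclose(np.abs(interior), 2e-4, rtol=1e-6)


def test_ridge_crest_scores_above_flanks():
    jj = np.arange(41, dtype=float)
    ridge = 500.0 * np.exp(-(((jj - 20.0) / 6.0) ** 2))
    dem = RasterGrid(np.tile(ridge, (21, 1)), cell_size=30.0)
    curv = max_curvature(dem, window_radius=120.0)
    crest = curv.values[10, 20]
    flank = curv.values[10, 12]
    assert crest > flank
    assert crest > 0  # convex-up crest is positive under the sign convention


def test_barrier_count_exact_and_value():
    rng = np.random.default_rng(1)
    curv = RasterGrid(rng.normal(size=(10, 10)), cell_size=30.0)
    mcr = barrier_raster(curv, top_fraction=0.2, barrier_value=300.0)
    assert (mcr.values == 300.0).sum() == 20
    assert set(np.unique(mcr.values)) == {0.0, 300.0}
    # flagged cells are exactly the top-20 values
    top20 = np.sort(curv.values.ravel())[-20:]
    assert np.sort(curv.values[mcr.values == 300.0]) == pytest.approx(np.sort(top20))


def test_barrier_ties_broken_row_major():
    vals = np.zeros((4, 5))  # all equal: first k cells in row-major order win
    mcr = barrier_raster(RasterGrid(vals), top_fraction=0.2, barrier_value=300.0)
    flagged = np.flatnonzero(mcr.values.ravel() == 300.0)
    assert list(flagged) == [0, 1, 2, 3]


def test_barrier_monotone_in_top_fraction():
    rng = np.random.default_rng(2)
    curv = RasterGrid(rng.normal(size=(15, 15)))
    prev = np.zeros((15, 15), dtype=bool)
    for frac in (0.1, 0.3, 0.6, 0.9):
        mask = barrier_raster(curv, frac).values > 0
        assert (mask | ~prev).all()  # flagged sets are nested
        prev = mask


def test_cost_surface_values(flat_dem):
    slope = compute_slope(flat_dem)
    d_a = slope_corrected_distance(slope, 30.0)
    mcr = RasterGrid(np.zeros((9, 9)))
    mcr.values[4, 4] = 300.0
    cs = cost_surface(d_a, mcr)
    assert cs.values[0, 0] == pytest.approx(30.0)
    assert cs.values[4, 4] == pytest.approx(330.0)


# ---------------------------------------------------------------------------
# cost distance
# ---------------------------------------------------------------------------

def _nx_cost_distance(cost, sources):
    """Independent oracle: Dijkstra over the 8-connected graph in networkx."""
    import networkx as nx

    nr, nc = cost.shape
    G = nx.Graph()
    for i in range(nr):
        for j in range(nc):
            for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < nr and 0 <= nj < nc:
                    w = (cost[i, j] + cost[ni, nj]) / 2.0
                    w *= math.sqrt(2.0) if di and dj else 1.0
                    G.add_edge((i, j), (ni, nj), weight=w)
    dist = nx.multi_source_dijkstra_path_length(G, sources)
    out = np.full((nr, nc), np.inf)
    for (i, j), d in dist.items():
        out[i, j] = d
    return out


def test_cost_distance_uniform_strip():
    cost = RasterGrid(np.full((1, 5), 30.0))
    src = np.zeros((1, 5), dtype=bool)
    src[0, 0] = True
    d = cost_distance(cost, src)
    np.testing.assert_allclose(d.values[0], [0, 30, 60, 90, 120])


def test_cost_distance_diagonal():
    cost = RasterGrid(np.full((5, 5), 30.0))
    src = np.zeros((5, 5), dtype=bool)
    src[2, 2] = True
    d = cost_distance(cost, src)
    assert d.values[0, 0] == pytest.approx(2 * 30.0 * math.sqrt(2.0))
    assert d.values[4, 4] == pytest.approx(2 * 30.0 * math.sqrt(2.0))


def test_cost_distance_matches_networkx_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        cost = rng.uniform(10.0, 300.0, size=(6, 6))
        src = np.zeros((6, 6), dtype=bool)
        src[tuple(rng.integers(0, 6, size=2))] = True
        got = cost_distance(RasterGrid(cost), src)
        want = _nx_cost_distance(cost, {tuple(np.argwhere(src)[0])})
        np.testing.assert_allclose(got.values, want, rtol=1e-9)


def test_barrier_wall_slows_propagation():
    cost = np.full((5, 9), 30.0)
    walled = cost.copy()
    walled[:, 4] += 300.0
    src = np.zeros((5, 9), dtype=bool)
    src[:, 0] = True
    d_free = cost_distance(RasterGrid(cost), src)
    d_wall = cost_distance(RasterGrid(walled), src)
    # far side of the wall is delayed by at least ~the barrier value
    assert (d_wall.values[:, 5:] - d_free.values[:, 5:] >= 299.0).all()
    # no cell ever gets closer when a barrier is added (monotonicity)
    assert (d_wall.values >= d_free.values - 1e-9).all()


def test_cost_distance_admissibility_bound():
    rng = np.random.default_rng(9)
    cost = rng.uniform(20.0, 90.0, size=(8, 8))
    src = np.zeros((8, 8), dtype=bool)
    src[0, 0] = True
    d = cost_distance(RasterGrid(cost), src)
    cmin = cost.min()
    for i in range(8):
        for j in range(8):
            chebyshev = max(i, j)
            assert d.values[i, j] >= chebyshev * cmin - 1e-9


def test_cost_distance_errors():
    cost = RasterGrid(np.full((3, 3), 30.0))
    with pytest.raises(ValueError, match="source"):
        cost_distance(cost, np.zeros((3, 3), dtype=bool))
    bad = RasterGrid(np.zeros((3, 3)))
    src = np.zeros((3, 3), dtype=bool)
    src[0, 0] = True
    with pytest.raises(ValueError, match="positive"):
        cost_distance(bad, src)


# ---------------------------------------------------------------------------
# D8 hydrology
# ---------------------------------------------------------------------------

def test_ramp_flows_east_and_accumulates():
    cols = np.arange(10)[::-1] * 10.0  # dips eastward
    dem = RasterGrid(np.tile(cols, (6, 1)), cell_size=30.0)
    fdir = flow_direction(fill_pits(dem))
    assert (fdir.values[:, :-1] == 0).all()  # 0 encodes east
    acc = flow_accumulation(fdir)
    np.testing.assert_array_equal(acc.values, np.tile(np.arange(10), (6, 1)))


def test_v_valley_accumulation_on_axis():
    # valley along the middle column of a southward-dipping trough
    nr, nc = 12, 11
    ii, jj = np.mgrid[0:nr, 0:nc].astype(float)
    dem = RasterGrid(np.abs(jj - 5.0) * 50.0 + (nr - ii) * 5.0, cell_size=30.0)
    fdir = flow_direction(fill_pits(dem))
    acc = flow_accumulation(fdir)
    for row in acc.values:
        assert row.argmax() == 5
    # brute-force upstream count at the valley outlet
    assert acc.values[-1, 5] == _brute_upstream_count(fdir.values, (nr - 1, 5))


def _brute_upstream_count(fdir, target):
    from ecoserv.terrain import D8_OFFSETS

    nr, nc = fdir.shape
    count = 0
    for i in range(nr):
        for j in range(nc):
            r, c = i, j
            seen = 0
            while (r, c) != target and fdir[r, c] >= 0 and seen < nr * nc:
                dr, dc = D8_OFFSETS[int(fdir[r, c])]
                r, c = r + dr, c + dc
                seen += 1
            if (r, c) == target and (i, j) != target:
                count += 1
    return count


def test_pit_filling_removes_depressions():
    rng = np.random.default_rng(3)
    dem = RasterGrid(rng.uniform(500, 600, size=(25, 25)), cell_size=30.0)
    filled = fill_pits(dem)
    assert (filled.values >= dem.values - 1e-9).all()
    fdir = flow_direction(filled)
    assert (fdir.values >= -1).all()  # every cell routed or an outlet


def test_accumulation_mass_balance():
    """Sum over terminals of (acc + 1) equals the number of valid cells."""
    rng = np.random.default_rng(8)
    dem = RasterGrid(rng.uniform(500, 700, size=(20, 20)), cell_size=30.0)
    fdir = flow_direction(fill_pits(dem))
    acc = flow_accumulation(fdir)
    terminals = fdir.values == -1
    assert (acc.values[terminals] + 1).sum() == dem.values.size


def test_watersheds_respect_minimum_area():
    dem = RasterGrid(
        np.random.default_rng(4).uniform(500, 2000, size=(150, 150)), cell_size=30.0
    )
    _, _, ws = d8_hydrology(dem, min_area_km2=2.0)
    labels, counts = np.unique(ws.values[ws.values > 0], return_counts=True)
    assert len(labels) >= 2
    min_cells = 2.0 * 1e6 / 30.0**2
    assert counts.min() >= min_cells


def test_tiny_grid_is_single_watershed(flat_dem):
    _, _, ws = d8_hydrology(flat_dem, min_area_km2=36.0)
    assert set(np.unique(ws.values)) == {1}
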