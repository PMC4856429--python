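"""USLE soil loss, LS factor, and mass-conserving sediment routing."""

import numpy as np
import pandas as pd
import pytest

from ecoserv import LandscapeSpec, RasterGrid, generate_landscape
from ecoserv.sediment import (
    USLEFactors,
    build_usle_factors,
    sediment_retention,
    soil_loss,
    usle_ls,
    watershed_export_table,
)
from ecoserv.terrain import d8_hydrology, fill_pits, flow_accumulation, flow_direction


def _factors(shape, R=1.0, K=1.0, LS=1.0, C=1.0, P=1.0, FILT=0.0):
    mk = lambda v: RasterGrid(np.full(shape, float(v)))  # noqa: E731
    return USLEFactors(mk(R), mk(K), mk(LS), mk(C), mk(P), mk(FILT))


def test_flat_dem_ls_is_baseline():
    dem = RasterGrid(np.full((5, 5), 800.0), cell_size=30.0)
    acc = RasterGrid(np.zeros((5, 5)))
    ls = usle_ls(dem, acc)
    # zero slope: L = 1, S = 0.03
    assert np.allclose(ls.values, 0.03, atol=1e-12)


def test_ls_monotone_in_slope():
    acc = RasterGrid(np.zeros((1, 5)))
    gentle = RasterGrid(np.arange(5.0).reshape(1, 5) * 5.0, cell_size=30.0)
    steep = RasterGrid(np.arange(5.0).reshape(1, 5) * 20.0, cell_size=30.0)
    assert usle_ls(steep, acc).values[0, 2] > usle_ls(gentle, acc).values[0, 2]


def test_ls_increases_downslope_on_ramp():
    """On a uniform 1xN ramp, LS grows with accumulated upstream area."""
    dem = RasterGrid(np.arange(5.0)[::-1].reshape(1, 5) * 15.0, cell_size=30.0)
    fdir = flow_direction(fill_pits(dem))
    acc = flow_accumulation(fdir)
    ls = usle_ls(dem, acc)
    assert (np.diff(ls.values[0, :-1]) > 0).all()


def test_soil_loss_product():
    f = _factors((1, 1), R=5000.0, K=0.01, LS=2.0, C=0.1, P=1.0)
    assert soil_loss(f).values[0, 0] == pytest.approx(10.0)


def test_soil_loss_annihilated_by_full_cover():
    f = _factors((3, 3), R=5000.0, K=0.02, LS=1.5, C=0.0)
    assert (soil_loss(f).values == 0).all()


def test_soil_loss_linear_in_erosivity():
    f1 = _factors((2, 2), R=1000.0, K=0.02, LS=1.5, C=0.5)
    f2 = _factors((2, 2), R=2000.0, K=0.02, LS=1.5, C=0.5)
    np.testing.assert_allclose(2 * soil_loss(f1).values, soil_loss(f2).values)


def test_three_cell_chain_hand_routing():
    """Bare eroding cell -> filtering forest cell -> outlet."""
    dem = RasterGrid(np.array([[30.0, 20.0, 10.0]]), cell_size=30.0)
    fdir = flow_direction(fill_pits(dem))
    mk = lambda v: RasterGrid(np.array([v]))  # noqa: E731
    f = USLEFactors(
        R=mk([100.0, 100.0, 100.0]), K=mk([0.1, 0.1, 0.1]), LS=mk([1.0, 1.0, 1.0]),
        C=mk([1.0, 0.01, 0.01]), P=mk([1.0, 1.0, 1.0]), FILT=mk([0.0, 0.6, 0.6]),
    )
    retention, export, intercepted = sediment_retention(f, fdir)
    a = soil_loss(f).values[0]
    # middle cell: avoided = R*K*LS*(1-C*P) = 10*(1-0.01) = 9.9, plus 0.6*A(0)
    assert intercepted.values[0, 1] == pytest.approx(0.6 * a[0])
    assert retention.values[0, 1] == pytest.approx(9.9 + 0.6 * a[0])
    # outlet export: its own loss + unfiltered upstream passing through
    passing_1 = a[1] + 0.4 * a[0]
    assert export.values[0, 2] == pytest.approx(a[2] + 0.4 * passing_1)


def test_no_filtration_means_no_interception():
    rng = np.random.default_rng(0)
    dem = RasterGrid(rng.uniform(100, 200, (8, 8)), cell_size=30.0)
    fdir = flow_direction(fill_pits(dem))
    f = _factors((8, 8), R=100.0, K=0.1, LS=1.0, C=0.5, FILT=0.0)
    retention, export, intercepted = sediment_retention(f, fdir)
    assert np.allclose(intercepted.values, 0.0)
    # pure-transport limit: everything generated leaves at the outlets
    assert export.valid_values().sum() == pytest.approx(soil_loss(f).valid_values().sum())


def test_mass_balance_on_random_landscapes():
    """Interception + outlet export equals total USLE loss (rel err < 1e-6)."""
    rng = np.random.default_rng(42)
    for _ in range(5):
        dem = RasterGrid(rng.uniform(500, 900, (20, 20)), cell_size=30.0)
        fdir = flow_direction(fill_pits(dem))
        f = _factors((20, 20))
        f = USLEFactors(
            R=RasterGrid(rng.uniform(1000, 9000, (20, 20))),
            K=RasterGrid(rng.uniform(0.005, 0.05, (20, 20))),
            LS=RasterGrid(rng.uniform(0.03, 5.0, (20, 20))),
            C=RasterGrid(rng.uniform(0, 1, (20, 20))),
            P=RasterGrid(rng.uniform(0, 1, (20, 20))),
            FILT=RasterGrid(rng.uniform(0, 0.9, (20, 20))),
        )
        retention, export, intercepted = sediment_retention(f, fdir)
        total_a = soil_loss(f).valid_values().sum()
        got = export.valid_values().sum() + intercepted.valid_values().sum()
        assert got == pytest.approx(total_a, rel=1e-9)


def test_increasing_filtration_never_decreases_retention():
    rng = np.random.default_rng(3)
    dem = RasterGrid(rng.uniform(100, 400, (12, 12)), cell_size=30.0)
    fdir = flow_direction(fill_pits(dem))
    base = USLEFactors(
        R=RasterGrid(np.full((12, 12), 5000.0)), K=RasterGrid(np.full((12, 12), 0.02)),
        LS=RasterGrid(rng.uniform(0.1, 3.0, (12, 12))), C=RasterGrid(np.full((12, 12), 0.5)),
        P=RasterGrid(np.ones((12, 12))), FILT=RasterGrid(np.full((12, 12), 0.2)),
    )
    hi = USLEFactors(base.R, base.K, base.LS, base.C, base.P,
                     RasterGrid(np.full((12, 12), 0.7)))
    r_lo, *_ = sediment_retention(base, fdir)
    r_hi, *_ = sediment_retention(hi, fdir)
    assert r_hi.valid_values().sum() >= r_lo.valid_values().sum()
    assert (r_lo.values >= -1e-12).all() and (r_hi.values >= -1e-12).all()


def test_factor_assembly_and_export_table():
    land = generate_landscape(LandscapeSpec(n_rows=40, n_cols=40, seed=5))
    fdir, acc, ws = d8_hydrology(land.dem, min_area_km2=0.2)
    f = build_usle_factors(land.erosivity, land.soil, land.soil_k_table,
                           land.lulc, land.lulc_table, land.dem, acc)
    assert (f.K.valid_values() > 0).all()
    assert f.C.min() >= 0 and f.C.max() <= 1
    _, export, _ = sediment_retention(f, fdir)
    tab = watershed_export_table(export, ws)
    assert (tab.watershed_id > 0).all()
    assert tab.export.sum() == pytest.approx(export.valid_values().sum(), rel=1e-9)
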