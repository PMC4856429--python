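"""Habitat quality: impact decay, accessibility, degradation, quality."""

import math

import numpy as np
import pytest

from ecoserv import RasterGrid
from ecoserv.habitat import (
    DECAY_CONSTANT,
    ThreatLayer,
    accessibility_raster,
    build_threat_layers,
    habitat_quality,
    threat_impact,
    total_degradation,
)
from ecoserv.tables import LULCTable
import pandas as pd


def _grid(vals):
    return RasterGrid(np.asarray(vals, dtype=float))


def _mini_table():
    return LULCTable(pd.DataFrame({
        "code": [1, 5], "name": ["forest", "pasture"],
        "is_habitat": [1, 0], "is_threat": [0, 1],
        "d_max_m": [0, 2000.0], "weight": [0, 1.0],
    }))


@pytest.mark.parametrize(
    "dc,expected",
    [(0.0, 1.0), (2000.0, math.exp(-2.99)), (4000.0, math.exp(-2.99) ** 2)],
)
def test_threat_impact_decay(dc, expected):
    """Impact is 1 at the source, ~5% at d_max, and squares at 2*d_max."""
    i = threat_impact(_grid([[dc]]), d_max=2000.0)
    assert i.values[0, 0] == pytest.approx(expected, rel=1e-12)


def test_decay_constant_is_five_percent_at_dmax():
    assert math.exp(-DECAY_CONSTANT) == pytest.approx(0.05, abs=0.0005)


def test_threat_impact_rejects_bad_dmax():
    with pytest.raises(ValueError):
        threat_impact(_grid([[0.0]]), d_max=0.0)


def test_unreachable_cells_have_zero_impact():
    i = threat_impact(_grid([[0.0, np.inf]]), d_max=1000.0)
    assert i.values[0, 1] == 0.0


def test_accessibility_labels():
    protected = RasterGrid(np.array([[0, 1, 2]], dtype=np.int64))
    beta = accessibility_raster(protected, strict_factor=0.5)
    np.testing.assert_allclose(beta.values, [[1.0, 0.5, 1.0]])


def test_accessibility_unknown_label_rejected():
    protected = RasterGrid(np.array([[0, 7]], dtype=np.int64))
    with pytest.raises(ValueError, match="label"):
        accessibility_raster(protected)


def test_degradation_weighted_sum_and_protection():
    beta = accessibility_raster(RasterGrid(np.array([[0, 1]], dtype=np.int64)), 0.5)
    shape_grid = _grid([[0.0, 0.0]])
    t1 = ThreatLayer(5, 1000.0, 3.0, shape_grid, _grid([[1.0, 1.0]]))
    t2 = ThreatLayer(6, 1000.0, 1.0, shape_grid, _grid([[0.0, 0.0]]))
    d = total_degradation([t1, t2], beta)
    # weights 3:1, impacts 1 and 0 -> D = 0.75 unprotected, halved inside
    assert d.values[0, 0] == pytest.approx(0.75)
    assert d.values[0, 1] == pytest.approx(0.375)


def test_degradation_weight_normalization_invariance():
    beta = accessibility_raster(RasterGrid(np.zeros((1, 2), dtype=np.int64)))
    g = _grid([[0.3, 0.8]])
    layers = [ThreatLayer(5, 1000.0, 2.0, g, g), ThreatLayer(6, 500.0, 1.0, g, g)]
    doubled = [ThreatLayer(t.class_code, t.d_max, 2 * t.weight, t.dc, t.impact) for t in layers]
    np.testing.assert_allclose(
        total_degradation(layers, beta).values,
        total_degradation(doubled, beta).values,
    )


@pytest.mark.parametrize("d,expected", [(0.0, 1.0), (0.5, 0.5), (1.0, 1.0 / 3.0)])
def test_habitat_quality_half_saturation(d, expected):
    lulc = RasterGrid(np.array([[1]], dtype=np.int64))
    q = habitat_quality(_grid([[d]]), lulc, _mini_table())
    assert q.values[0, 0] == pytest.approx(expected)


def test_non_habitat_cells_have_zero_quality():
    lulc = RasterGrid(np.array([[1, 5]], dtype=np.int64))
    q = habitat_quality(_grid([[0.0, 0.0]]), lulc, _mini_table())
    np.testing.assert_allclose(q.values, [[1.0, 0.0]])


def test_end_to_end_strip_matches_scalar_oracle():
    """Pipeline Q on a 1-threat strip equals a hand-rolled scalar oracle."""
    n = 12
    lulc = RasterGrid(np.array([[5] + [1] * (n - 1)], dtype=np.int64))
    cost = RasterGrid(np.full((1, n), 30.0))
    table = _mini_table()
    layers = build_threat_layers(lulc, cost, table)
    beta = accessibility_raster(RasterGrid(np.zeros((1, n), dtype=np.int64)))
    d = total_degradation(layers, beta)
    q = habitat_quality(d, lulc, table)
    for j in range(n):
        dc = 30.0 * j  # uniform flat cost, sources at column 0
        i = math.exp(-(2.99 / 2000.0) * dc)
        dd = i  # single threat, weight normalizes to 1, beta 1
        expect = 0.0 if j == 0 else 1.0 - dd / (dd + 0.5)
        assert q.values[0, j] == pytest.approx(expect, abs=1e-9)


def test_quality_monotone_with_distance_from_threat():
    n = 20
    lulc = RasterGrid(np.array([[5] + [1] * (n - 1)], dtype=np.int64))
    cost = RasterGrid(np.full((1, n), 30.0))
    table = _mini_table()
    layers = build_threat_layers(lulc, cost, table)
    beta = accessibility_raster(RasterGrid(np.zeros((1, n), dtype=np.int64)))
    q = habitat_quality(total_degradation(layers, beta), lulc, table)
    assert (np.diff(q.values[0, 1:]) >= -1e-12).all()


def test_no_threats_on_map_is_an_error():
    lulc = RasterGrid(np.ones((2, 2), dtype=np.int64))
    cost = RasterGrid(np.full((2, 2), 30.0))
    with pytest.raises(ValueError):
        build_threat_layers(lulc, cost, _mini_table())


def test_barrier_never_hurts_far_side_quality():
    """Inserting a curvature barrier between threat and habitat never
    decreases Q beyond the barrier."""
    n = 15
    lulc = RasterGrid(np.array([[5] + [1] * (n - 1)], dtype=np.int64))
    flat = np.full((1, n), 30.0)
    walled = flat.copy()
    walled[0, 7] += 300.0
    table = _mini_table()
    beta = accessibility_raster(RasterGrid(np.zeros((1, n), dtype=np.int64)))

    def quality(cost_vals):
        layers = build_threat_layers(lulc, RasterGrid(cost_vals), table)
        return habitat_quality(total_degradation(layers, beta), lulc, table)

    q_free = quality(flat)
    q_wall = quality(walled)
    assert (q_wall.values[0, 8:] >= q_free.values[0, 8:] - 1e-12).all()
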