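"""USLE soil loss and sediment retention with D8 routing and filtration.

Annual soil loss per cell (ton/ha/yr) follows the Universal Soil Loss
Equation,

    A = R * K * LS * C * P,

with rainfall erosivity R, soil erodibility K (looked up per soil code),
the Desmet–Govers slope-length/gradient factor LS, and per-LULC-class
cover-management C and support-practice P factors.

Retention has two parts: on-site avoided erosion, ``R*K*LS*(1 - C*P)`` (what
the cover prevents relative to bare fallow), and interception of the
sediment arriving from upstream.  Loads are routed cell-to-cell along D8
flow directions in upstream-first order; at each cell a class-specific
fraction ``filt_eff`` of the incoming load is trapped and credited to that
cell's retention, the rest passes downstream, and whatever reaches a
terminal cell leaves the landscape as export.  The scheme conserves mass:
sum(export) + sum(intercepted) = sum(A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RasterGrid, joint_valid_mask, require_aligned
from .tables import LULCTable
from .terrain import D8_OFFSETS, compute_slope

log = logging.getLogger(__name__)

#: Desmet–Govers / McCool constants (exposed for configuration).
LS_REFERENCE_LENGTH_M = 22.13
MCCOOL_GENTLE = (10.8, 0.03)   # S = 10.8 sin(theta) + 0.03 below 9% slope
MCCOOL_STEEP = (16.8, -0.50)   # S = 16.8 sin(theta) - 0.50 at 9% and above
MCCOOL_BREAK_TAN = 0.09


@dataclass
class USLEFactors:
    """Aligned per-cell USLE factor rasters plus the filtration raster."""

    R: RasterGrid
    K: RasterGrid
    LS: RasterGrid
    C: RasterGrid
    P: RasterGrid
    FILT: RasterGrid

    def grids(self) -> dict[str, RasterGrid]:
        return {"R": self.R, "K": self.K, "LS": self.LS, "C": self.C, "P": self.P,
                "FILT": self.FILT}


def usle_ls(dem: RasterGrid, flow_acc: RasterGrid) -> RasterGrid:
    """Desmet–Govers LS factor from slope and contributing area.

    The length factor L uses the unit contributing area at the cell inlet
    (upstream cell count times cell area); the slope factor S is McCool's
    two-piece form.  Flat cells with no upstream area reduce to the
    formulation's baseline (L = 1, S = 0.03).
    """
    require_aligned(dem, flow_acc)
    theta = np.radians(compute_slope(dem).filled(0.0))
    sin_t = np.sin(theta)
    beta = (sin_t / 0.0896) / (3.0 * sin_t**0.8 + 0.56)
    m = beta / (1.0 + beta)
    d = dem.cell_size
    area_in = flow_acc.filled(0.0) * d * d  # m^2 of upstream area at the inlet
    with np.errstate(invalid="ignore"):
        num = (area_in + d * d) ** (m + 1.0) - area_in ** (m + 1.0)
        den = d ** (m + 2.0) * LS_REFERENCE_LENGTH_M**m
        L = num / den
    s_gentle = MCCOOL_GENTLE[0] * sin_t + MCCOOL_GENTLE[1]
    s_steep = MCCOOL_STEEP[0] * sin_t + MCCOOL_STEEP[1]
    S = np.where(np.tan(theta) < MCCOOL_BREAK_TAN, s_gentle, s_steep)
    bad = ~(dem.valid_mask & flow_acc.valid_mask)
    return dem.like(L * S, nodata_mask=bad)


def build_usle_factors(
    erosivity: RasterGrid,
    soil: RasterGrid,
    soil_k: pd.DataFrame,
    lulc: RasterGrid,
    table: LULCTable,
    dem: RasterGrid,
    flow_acc: RasterGrid,
) -> USLEFactors:
    """Assemble the six aligned factor rasters from maps and lookup tables."""
    require_aligned(erosivity, soil, lulc, dem, flow_acc)
    valid = joint_valid_mask(erosivity, soil, lulc, dem, flow_acc)
    codes = np.where(valid, lulc.values, table.codes[0])

    k_lut = np.full(int(soil_k.soil_code.max()) + 1, np.nan)
    k_lut[soil_k.soil_code.to_numpy()] = soil_k.k_factor.to_numpy(dtype=float)
    soil_codes = np.where(valid, soil.values, soil_k.soil_code.iloc[0]).astype(int)
    if soil_codes.max() >= len(k_lut) or np.isnan(k_lut[soil_codes]).any():
        present = set(np.unique(soil_codes)) - set(soil_k.soil_code)
        raise KeyError(f"soil codes missing from K table: {sorted(present)}")

    mk = lambda arr: lulc.like(arr, nodata_mask=~valid)  # noqa: E731
    ls = usle_ls(dem, flow_acc)
    return USLEFactors(
        R=mk(erosivity.filled(0.0)),
        K=mk(k_lut[soil_codes]),
        LS=mk(ls.filled(0.0)),
        C=mk(table.column_for(codes, "usle_c")),
        P=mk(table.column_for(codes, "usle_p")),
        FILT=mk(table.column_for(codes, "filt_eff")),
    )


def soil_loss(factors: USLEFactors) -> RasterGrid:
    """Annual soil loss A = R*K*LS*C*P (ton/ha/yr) per cell."""
    f = factors
    require_aligned(f.R, f.K, f.LS, f.C, f.P)
    a = f.R.filled(0.0) * f.K.filled(0.0) * f.LS.filled(0.0) * f.C.filled(0.0) * f.P.filled(0.0)
    bad = ~joint_valid_mask(f.R, f.K, f.LS, f.C, f.P)
    return f.R.like(a, nodata_mask=bad)


def _downstream_map(flow_dir: RasterGrid) -> np.ndarray:
    """Flat index of each cell's downstream cell; -1 for terminals/nodata."""
    fdir = flow_dir.values.astype(np.int64)
    nr, nc = fdir.shape
    down = np.full(nr * nc, -1, dtype=np.int64)
    flat = fdir.ravel()
    ids = np.flatnonzero(flow_dir.valid_mask.ravel() & (flat >= 0))
    drs = np.array([o[0] for o in D8_OFFSETS])
    dcs = np.array([o[1] for o in D8_OFFSETS])
    d = flat[ids]
    down[ids] = (ids // nc + drs[d]) * nc + (ids % nc + dcs[d])
    return down


def sediment_retention(
    factors: USLEFactors,
    flow_dir: RasterGrid,
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Route sediment and credit retention.

    Returns ``(retention, export, intercepted)`` rasters, all in the units of
    :func:`soil_loss` (ton/ha/yr per cell):

    * ``retention`` — on-site avoided erosion plus intercepted upstream load;
    * ``export`` — load leaving the landscape, nonzero only on terminal cells;
    * ``intercepted`` — the interception component alone.
    """
    f = factors
    require_aligned(f.R, flow_dir)
    a = soil_loss(f)
    valid = a.valid_mask & flow_dir.valid_mask
    nr, nc = a.shape
    n = nr * nc
    gen = np.where(valid, a.filled(0.0), 0.0).ravel()
    filt = np.where(valid, f.FILT.filled(0.0), 0.0).ravel()
    down = _downstream_map(flow_dir)
    down[~valid.ravel()] = -1

    indeg = np.bincount(down[down >= 0], minlength=n)
    incoming = np.zeros(n)
    export = np.zeros(n)
    stack = list(np.flatnonzero(valid.ravel() & (indeg == 0)))
    while stack:
        u = stack.pop()
        passing = gen[u] + (1.0 - filt[u]) * incoming[u]
        v = down[u]
        if v < 0:
            export[u] = passing
        else:
            incoming[v] += passing
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)

    avoided = (f.R.filled(0.0) * f.K.filled(0.0) * f.LS.filled(0.0)
               * (1.0 - f.C.filled(0.0) * f.P.filled(0.0)))
    intercepted = (filt * incoming).reshape(nr, nc)
    retention = np.where(valid, avoided + intercepted, 0.0)
    mk = lambda arr: a.like(arr, nodata_mask=~valid)  # noqa: E731
    return mk(retention), mk(export.reshape(nr, nc)), mk(intercepted)


def watershed_export_table(export: RasterGrid, watershed_id: RasterGrid) -> pd.DataFrame:
    """Total export per labeled sub-watershed (load units x cell count)."""
    require_aligned(export, watershed_id)
    valid = export.valid_mask & watershed_id.valid_mask
    ws = watershed_id.values[valid].astype(int)
    ex = export.values[valid].astype(float)
    df = pd.DataFrame({"watershed_id": ws, "export": ex})
    out = df.groupby("watershed_id", as_index=False)["export"].sum()
    return out[out.watershed_id > 0].reset_index(drop=True)
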