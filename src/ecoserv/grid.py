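"""Raster grid container used by every stage of the pipeline.

A :class:`RasterGrid` is a rectangular array of numeric cell values with a
cell size in meters, a world-coordinate origin, and a nodata sentinel.  It is
deliberately minimal: no CRS, single band, (row, col) indexing with row 0 at
the top.  World coordinates refer to cell centers; ``origin`` is the outer
corner of the top-left cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Default nodata sentinel for float rasters.
DEFAULT_NODATA = -9999.0


class AlignmentError(ValueError):
    """Two grids entering a binary operation do not share a geometry."""


@dataclass
class RasterGrid:
    """Rectangular numeric grid with cell size, origin and nodata sentinel.

    Parameters
    ----------
    values
        2-D array of cell values.  Stored as ``float64`` unless the input is
        an integer array, which is preserved (integer rasters such as LULC
        codes must round-trip exactly).
    cell_size
        Edge length of a (square) cell, in meters.  Must be positive.
    origin
        ``(x, y)`` world coordinate of the outer corner of the top-left cell.
    nodata
        Sentinel excluded from all statistics and propagated through
        arithmetic.
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic geometry ----------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares."""
        return self.cell_size**2 / 10_000.0

    @property
    def cell_area_km2(self) -> float:
        """Area of one cell in square kilometers."""
        return self.cell_size**2 / 1e6

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """World coordinate of a cell center (x east, y north; row 0 on top)."""
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    # -- nodata handling ---------------------------------------------------
    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        v = self.values
        if np.issubdtype(v.dtype, np.floating):
            return ~np.isclose(v, self.nodata) & ~np.isnan(v)
        return v != self.nodata

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        """1-D array of the values at valid cells."""
        return self.values[self.valid_mask]

    def filled(self, fill: float = np.nan) -> np.ndarray:
        """Float copy of the values with nodata replaced by ``fill``."""
        out = self.values.astype(float, copy=True)
        out[~self.valid_mask] = fill
        return out

    # -- derived grids -----------------------------------------------------
    def like(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid with this geometry carrying ``values``.

        ``nodata_mask`` marks cells to blank out; by default the current
        invalid cells are blanked (nodata propagation).
        """
        values = np.asarray(values)
        if values.shape != self.shape:
            raise AlignmentError(
                f"replacement values have shape {values.shape}, grid is {self.shape}"
            )
        if nodata_mask is None:
            nodata_mask = ~self.valid_mask
        if nodata_mask.any():
            values = values.astype(float, copy=True)
            values[nodata_mask] = self.nodata
        return RasterGrid(values, self.cell_size, self.origin, self.nodata)

    def copy(self) -> "RasterGrid":
        return replace(self, values=self.values.copy())

    # -- statistics (valid cells only) --------------------------------------
    def min(self) -> float:
        return float(self.valid_values().min())

    def max(self) -> float:
        return float(self.valid_values().max())

    def mean(self) -> float:
        return float(self.valid_values().mean())


def align_check(grids: list[RasterGrid] | tuple[RasterGrid, ...]) -> bool:
    """True iff all grids share shape, cell size and origin.

    Every multi-raster stage uses this predicate as a guard.  Reflexive and
    symmetric by construction.
    """
    if not grids:
        raise ValueError("align_check requires a nonempty list of grids")
    ref = grids[0]
    return all(
        g.shape == ref.shape
        and np.isclose(g.cell_size, ref.cell_size)
        and np.allclose(g.origin, ref.origin)
        for g in grids[1:]
    )


def require_aligned(*grids: RasterGrid) -> None:
    """Raise :class:`AlignmentError` unless all grids are mutually aligned."""
    if not align_check(list(grids)):
        detail = ", ".join(
            f"(shape={g.shape}, cell={g.cell_size}, origin={g.origin})" for g in grids
        )
        raise AlignmentError(f"grids are not aligned: {detail}")


def joint_valid_mask(*grids: RasterGrid) -> np.ndarray:
    """Cells valid in every grid (the domain of any multi-raster operation)."""
    require_aligned(*grids)
    mask = grids[0].valid_mask
    for g in grids[1:]:
        mask = mask & g.valid_mask
    return mask
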