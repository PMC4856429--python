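"""Reading and writing raster grids.

Two dialects are supported:

``ascii_grid``
    ESRI ASCII grid (``.asc``) — a plain-text header (``ncols``, ``nrows``,
    ``xllcorner``, ``yllcorner``, ``cellsize``, ``NODATA_value``) followed by
    the cell values in row-major order, row 0 at the top.  The format of
    choice for small fixtures and text-only archives.

``geotiff``
    Single-band GeoTIFF via :mod:`tifffile`, carrying the pixel scale,
    tie-point and nodata in the standard GeoTIFF/GDAL tags.  No CRS is
    written or interpreted.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np

from .grid import DEFAULT_NODATA, RasterGrid

log = logging.getLogger(__name__)

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


class RasterFormatError(ValueError):
    """A raster file does not parse under the requested dialect."""


def _sniff_dialect(path: str | os.PathLike) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".asc", ".txt", ".grd"):
        return "ascii_grid"
    raise RasterFormatError(
        f"cannot infer raster dialect from extension {suffix!r}; pass dialect explicitly"
    )


def read_raster(path: str | os.PathLike, dialect: str | None = None) -> RasterGrid:
    """Read a raster grid from ``path``.

    ``dialect`` is ``"geotiff"`` or ``"ascii_grid"``; when omitted it is
    inferred from the file extension.
    """
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect == "ascii_grid":
        return _read_ascii(path)
    if dialect == "geotiff":
        return _read_geotiff(path)
    raise RasterFormatError(f"unknown raster dialect {dialect!r}")


def write_raster(grid: RasterGrid, path: str | os.PathLike, dialect: str | None = None) -> None:
    """Write ``grid`` to ``path`` under the given (or inferred) dialect."""
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect == "ascii_grid":
        _write_ascii(grid, path)
    elif dialect == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise RasterFormatError(f"unknown raster dialect {dialect!r}")


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def _read_ascii(path: str | os.PathLike) -> RasterGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _ASCII_HEADER_KEYS or key == "nodata_value":
                if len(parts) != 2:
                    raise RasterFormatError(f"malformed header line {line.rstrip()!r}")
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise RasterFormatError(f"non-numeric header field {key!r}") from exc
            else:
                try:
                    rows.append([float(tok) for tok in parts])
                except ValueError as exc:
                    raise RasterFormatError(f"non-numeric data token in line {line.rstrip()!r}") from exc
    for key in _ASCII_HEADER_KEYS:
        if key not in header:
            raise RasterFormatError(f"missing required header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(rows) != nrows:
        raise RasterFormatError(f"header declares nrows={nrows} but file has {len(rows)} data rows")
    for i, row in enumerate(rows):
        if len(row) != ncols:
            raise RasterFormatError(
                f"header declares ncols={ncols} but data row {i} has {len(row)} values"
            )
    values = np.array(rows, dtype=float)
    if np.allclose(values, values.astype(np.int64), atol=0) and np.abs(values).max(initial=0) < 2**62:
        values = values.astype(np.int64)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return RasterGrid(values, cell, origin, header.get("nodata_value", DEFAULT_NODATA))


def _write_ascii(grid: RasterGrid, path: str | os.PathLike) -> None:
    x0, y_top = grid.origin
    yll = y_top - grid.n_rows * grid.cell_size
    is_int = np.issubdtype(grid.values.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {x0:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        for row in grid.values:
            if is_int:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
            else:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# GeoTIFF (single band, via tifffile)
# ---------------------------------------------------------------------------

def _read_geotiff(path: str | os.PathLike) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise RasterFormatError(f"expected a single-band raster, got shape {values.shape}")
        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        tiepoint = tags.get(_TAG_TIEPOINT)
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        if scale is None or tiepoint is None:
            raise RasterFormatError("GeoTIFF lacks pixel-scale or tie-point tags")
        sx, sy = scale.value[0], scale.value[1]
        if not np.isclose(sx, sy):
            raise RasterFormatError(f"non-square cells ({sx} x {sy}) are not supported")
        # tie point maps raster (i, j, k) -> model (x, y, z); (0,0) -> origin
        origin = (float(tiepoint.value[3]), float(tiepoint.value[4]))
        nodata = float(nodata_tag.value) if nodata_tag is not None else DEFAULT_NODATA
    return RasterGrid(values, float(sx), origin, nodata)


def _write_geotiff(grid: RasterGrid, path: str | os.PathLike) -> None:
    import tifffile

    values = grid.values
    if np.issubdtype(values.dtype, np.integer):
        values = values.astype(np.int32)
    else:
        values = values.astype(np.float64)
    cs = float(grid.cell_size)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{grid.nodata:g}"),
    ]
    tifffile.imwrite(path, values, extratags=extratags)
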