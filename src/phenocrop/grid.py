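"""Raster grid container and plain-text raster I/O.

All rasters in a run share one affine grid: square cells, north-up, map
coordinates of the upper-left corner stored explicitly.  Rasters are
persisted as ESRI ASCII grids (``.asc``) with an optional ``.prj`` sidecar
carrying the CRS identifier, so every artifact the pipeline writes is
human-readable text.

Conventions: row/col indices are 0-based; the map coordinate of a cell
refers to its center; ``nodata`` is a sentinel compared only through
:meth:`RasterGrid.mask`, never by arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_raster", "write_raster"]

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band raster on a square-cell, north-up grid.

    Parameters
    ----------
    values
        2-D array (rows x cols); row 0 is the northern edge.
    cell_size
        Cell edge length in map units (meters); > 0.
    origin
        Map (x, y) of the upper-left corner of the upper-left cell.
    crs_id
        Free-form coordinate reference identifier (e.g. ``"EPSG:32638"``).
    nodata
        Sentinel marking invalid cells.
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def require_same_geometry(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.same_geometry(other):
            raise ValueError(f"geometry mismatch between {what}s: "
                             f"{self.shape}@{self.origin} vs {other.shape}@{other.origin}")

    def cell_area_km2(self) -> float:
        return (self.cell_size ** 2) / 1e6

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing map point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col

    def contains_point(self, x: float, y: float) -> bool:
        r, c = self.index_of(x, y)
        return 0 <= r < self.shape[0] and 0 <= c < self.shape[1]

    # -- values -------------------------------------------------------------

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return self.values != self.nodata

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_equal(self.values, self.nodata)

    def filled_nan(self) -> np.ndarray:
        """Float copy with nodata replaced by NaN (for numpy reductions)."""
        out = self.values.astype(float, copy=True)
        out[~self.mask] = np.nan
        return out

    def like(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """New grid with this geometry and the given values."""
        return replace(self, values=np.asarray(values),
                       nodata=self.nodata if nodata is None else nodata)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    """Write an ESRI ASCII grid (+ ``.prj`` sidecar with the CRS id).

    Integer-valued grids are written without a decimal point so the
    write/read cycle is bit-exact for integer data.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nrows, ncols = grid.shape
    x0, y0 = grid.origin
    yll = y0 - nrows * grid.cell_size
    vals = grid.values
    integral = np.issubdtype(vals.dtype, np.integer) or (
        np.issubdtype(vals.dtype, np.floating)
        and np.all(np.isfinite(vals))
        and np.all(vals == np.round(vals))
    )
    fmt = "%d" if integral else "%.10g"
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        nd = grid.nodata
        fh.write(f"NODATA_value {int(nd) if float(nd).is_integer() else nd}\n")
        np.savetxt(fh, np.atleast_2d(vals), fmt=fmt)
    if grid.crs_id and grid.crs_id != "local":
        Path(str(path) + ".prj").write_text(grid.crs_id + "\n")
    return path


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        m = re.match(r"^\s*([A-Za-z_]+)\s+(\S+)\s*$", line)
        if m and m.group(1).lower() in _HEADER_KEYS:
            header[m.group(1).lower()] = float(m.group(2))
        else:
            data_start = i
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: malformed ASCII grid header (missing {key})")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.loadtxt(lines[data_start:], ndmin=2)
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {values.shape} does not match "
                         f"header ({nrows}, {ncols})")
    if np.all(np.isfinite(values)) and np.all(values == np.round(values)):
        values = values.astype(np.int64)
    x0 = header.get("xllcorner", 0.0)
    y0 = header.get("yllcorner", 0.0) + nrows * cell
    prj = Path(str(path) + ".prj")
    crs_id = prj.read_text().strip() if prj.exists() else "local"
    return RasterGrid(values=values, cell_size=cell, origin=(x0, y0),
                      crs_id=crs_id, nodata=nodata)
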