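"""Landform metrics from digital elevation models.

Holds the regular-grid DEM container, ESRI ASCII grid I/O, the 3x3
finite-difference slope and curvature operators used throughout terrain
analysis, nearest-cell point extraction, the treeline elevation-deviation
response, and the mountain-mass index (area above an elevation threshold).

Conventions
-----------
* Grids are row-major north-to-south: row 0 is the northernmost row.
* Coordinates are projected metres (NZTM-like); the origin is the
  lower-left (south-west) corner of the grid.
* Curvature is reported in 1/(100 m) units, positive = convex — the scale
  used by the ArcGIS ``Curvature`` function, so published thresholds such
  as -0.24 are directly comparable.
* Border cells of the 3x3 operators, and any window touching a nodata
  cell, yield nodata.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEMGrid",
    "FormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "slope_percent",
    "curvature",
    "extract_at_points",
    "elevation_deviation",
    "mountain_mass_index",
]

DEFAULT_NODATA = -9999.0


class FormatError(ValueError):
    """Raised for malformed ESRI ASCII grid files."""


@dataclass
class DEMGrid:
    """Regular elevation raster.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Elevations in metres; cells equal to ``nodata_value`` are missing.
    cell_size : float
        Cell edge length in metres.
    origin_easting, origin_northing : float
        Coordinates of the lower-left *corner* of the grid, metres.
    nodata_value : float
        Sentinel for missing cells.
    """

    values: np.ndarray
    cell_size: float
    origin_easting: float = 0.0
    origin_northing: float = 0.0
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DEM values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        data = self.values[~self.nodata_mask]
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("non-nodata DEM cells must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata_value

    def masked(self) -> np.ndarray:
        """Values with nodata cells replaced by NaN."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(easting, northing) of a cell centre."""
        e = self.origin_easting + (col + 0.5) * self.cell_size
        n = self.origin_northing + (self.n_rows - row - 0.5) * self.cell_size
        return e, n

    def like(self, values: np.ndarray) -> "DEMGrid":
        """New grid sharing this grid's georeferencing."""
        return replace(self, values=np.asarray(values, dtype=float))

    def __eq__(self, other: object) -> bool:  # value equality incl. geo
        if not isinstance(other, DEMGrid):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
            and self.cell_size == other.cell_size
            and self.origin_easting == other.origin_easting
            and self.origin_northing == other.origin_northing
            and self.nodata_value == other.nodata_value
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> DEMGrid:
    """Read an ESRI ASCII grid (.asc) file.

    The header must provide ncols, nrows, xllcorner, yllcorner and
    cellsize; NODATA_value is optional (default -9999). Nodata cells keep
    the sentinel value in ``values``.
    """
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        key = parts[0].lower()
        if key in _HEADER_KEYS + ("nodata_value",):
            if len(parts) != 2:
                raise FormatError(f"malformed header line: {line!r}")
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"non-numeric header value: {line!r}") from exc
            body_start = i + 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"missing header keys: {', '.join(missing)}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if ncols < 1 or nrows < 1:
        raise FormatError("ncols and nrows must be positive")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    try:
        values = np.loadtxt(io.StringIO("\n".join(lines[body_start:])), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"ragged or non-numeric grid body: {exc}") from exc
    if values.size != nrows * ncols:
        raise FormatError(
            f"expected {nrows * ncols} values, found {values.size}"
        )
    if values.shape[1] != ncols:
        values = values.reshape(nrows, ncols)
    return DEMGrid(
        values=values,
        cell_size=header["cellsize"],
        origin_easting=header["xllcorner"],
        origin_northing=header["yllcorner"],
        nodata_value=nodata,
    )


def write_ascii_grid(dem: DEMGrid, path) -> None:
    """Write an ESRI ASCII grid; round-trips exactly through repr floats."""
    with open(path, "w") as fh:
        fh.write(f"ncols {dem.n_cols}\n")
        fh.write(f"nrows {dem.n_rows}\n")
        fh.write(f"xllcorner {float(dem.origin_easting)!r}\n")
        fh.write(f"yllcorner {float(dem.origin_northing)!r}\n")
        fh.write(f"cellsize {float(dem.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(dem.nodata_value)!r}\n")
        for row in dem.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# 3x3 window operators
# ---------------------------------------------------------------------------


def _windowed(dem: DEMGrid):
    """Return the 8 shifted neighbour views + centre for interior cells.

    Layout (GIS convention, row 0 = north):
        a b c
        d e f
        g h i
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("3x3 operators require a DEM of at least 3x3 cells")
    z = dem.masked()
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2]; e = z[1:-1, 1:-1]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    return a, b, c, d, e, f, g, h, i


def _finish(dem: DEMGrid, interior: np.ndarray, window_sum: np.ndarray) -> DEMGrid:
    # a NaN anywhere in the 3x3 window (tracked by window_sum) poisons the cell
    out = np.full_like(dem.values, dem.nodata_value)
    interior = np.where(
        np.isfinite(interior) & np.isfinite(window_sum), interior, dem.nodata_value
    )
    out[1:-1, 1:-1] = interior
    return dem.like(out)


def slope_percent(dem: DEMGrid) -> DEMGrid:
    """Slope gradient (%) by Horn's method.

    Rate of maximum change in elevation within each 3x3 neighbourhood:
    dz/dx = ((c + 2f + i) - (a + 2d + g)) / 8L,
    dz/dy = ((g + 2h + i) - (a + 2b + c)) / 8L,
    slope% = 100 * sqrt((dz/dx)^2 + (dz/dy)^2), with L the cell size.
    """
    a, b, c, d, e, f, g, h, i = _windowed(dem)
    eight_l = 8.0 * dem.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / eight_l
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / eight_l
    window_sum = a + b + c + d + e + f + g + h + i
    return _finish(dem, 100.0 * np.hypot(dzdx, dzdy), window_sum)


def curvature(dem: DEMGrid) -> DEMGrid:
    """General surface curvature (Zevenbergen–Thorne), 1/(100 m) units.

    A fourth-order polynomial is fitted to each 3x3 window; with the
    north/west/east/south rook neighbours Z2, Z4, Z6, Z8 and centre Z5:
    D = ((Z4 + Z6)/2 - Z5) / L^2, E = ((Z2 + Z8)/2 - Z5) / L^2,
    curvature = -2 (D + E) * 100.  Positive = convex, negative = concave.
    """
    a, z2, c, z4, z5, z6, g, z8, i = _windowed(dem)
    l2 = dem.cell_size**2
    dd = ((z4 + z6) / 2.0 - z5) / l2
    ee = ((z2 + z8) / 2.0 - z5) / l2
    window_sum = a + z2 + c + z4 + z5 + z6 + g + z8 + i
    return _finish(dem, -2.0 * (dd + ee) * 100.0, window_sum)


# ---------------------------------------------------------------------------
# Point extraction and the deviation response
# ---------------------------------------------------------------------------


def _point_cell(dem: DEMGrid, easting: float, northing: float) -> tuple[int, int]:
    x = (easting - dem.origin_easting) / dem.cell_size
    y = (northing - dem.origin_northing) / dem.cell_size
    if not (0.0 <= x <= dem.n_cols and 0.0 <= y <= dem.n_rows):
        raise ValueError("point outside DEM extent")
    # Nearest cell centre; boundary ties resolve to the smaller row index
    # (northernmost cell) then the smaller column index.
    col = int(np.clip(np.ceil(x) - 1, 0, dem.n_cols - 1))
    row_from_bottom = int(np.clip(np.floor(y), 0, dem.n_rows - 1))
    return dem.n_rows - 1 - row_from_bottom, col


def extract_at_points(grid: DEMGrid, points: pd.DataFrame, column: str = "value") -> pd.DataFrame:
    """Sample a grid at point locations (nearest cell).

    ``points`` needs ``easting`` and ``northing`` columns; the result is a
    copy with ``column`` holding the sampled values and ``<column>_nodata``
    flagging points that fell on nodata cells.

    Raises
    ------
    ValueError
        If a point lies outside the grid extent; the message names the
        offending point (its ``point_id`` when present, else its row label).
    """
    out = points.copy()
    vals = np.empty(len(points))
    nodata = np.zeros(len(points), dtype=bool)
    for k, (idx, rec) in enumerate(points.iterrows()):
        try:
            r, c = _point_cell(grid, float(rec["easting"]), float(rec["northing"]))
        except ValueError:
            name = rec["point_id"] if "point_id" in rec else idx
            raise ValueError(f"point {name!r} lies outside the grid extent") from None
        v = grid.values[r, c]
        if v == grid.nodata_value:
            nodata[k] = True
            vals[k] = np.nan
        else:
            vals[k] = v
    out[column] = vals
    out[f"{column}_nodata"] = nodata
    return out


def elevation_deviation(points: pd.DataFrame) -> pd.DataFrame:
    """Treeline elevation deviation from the site-level maximum.

    For every point the response is the site's maximum observed treeline
    elevation minus the point's elevation, so each site's highest treeline
    point has deviation 0 and all deviations are >= 0.

    ``points`` needs ``site_id`` and ``elevation`` columns; returns a copy
    with ``site_max_elevation`` and ``elevation_deviation`` added.
    """
    if "site_id" not in points or "elevation" not in points:
        raise ValueError("points require 'site_id' and 'elevation' columns")
    if points.empty:
        raise ValueError("no points supplied")
    if points["elevation"].isna().any():
        raise ValueError("all point elevations must be populated")
    out = points.copy()
    out["site_max_elevation"] = out.groupby("site_id")["elevation"].transform("max")
    out["elevation_deviation"] = out["site_max_elevation"] - out["elevation"]
    return out


def mountain_mass_index(dem: DEMGrid, threshold: float = 1200.0) -> float:
    """Area (km^2) above an elevation threshold — a mountain-mass proxy.

    Larger massifs elevate regional thermal limits (the mountain-mass
    effect); the default 1,200 m threshold targets the subalpine zone.
    """
    mask = ~dem.nodata_mask & (dem.values > threshold)
    return float(mask.sum()) * dem.cell_size**2 / 1e6
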