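"""Reading and writing GPS fix tables and elevation rasters.

Fix tables use a Movebank-style CSV dialect (one row per fix, ISO-8601
timestamps, geographic or planar coordinates).  Internally every track is a
:class:`pandas.DataFrame` with columns ``individual`` (str), ``time``
(timezone-naive local datetime), ``x``/``y`` (planar metres, east/north) and
``regime`` (``hires`` | ``burst`` | ``sparse``).

Elevation rasters are plain ESRI ASCII grids (``.asc``).  Geographic
coordinates are projected to planar metres with a local transverse-Mercator
projection centred on the data extent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIMES = ("hires", "burst", "sparse")

# canonical column names of the CSV dialect
COL_ID = "individual-local-identifier"
COL_TIME = "timestamp"
COL_LON = "location-long"
COL_LAT = "location-lat"
COL_X = "x"
COL_Y = "y"
COL_REGIME = "regime"


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563


@dataclass
class TransverseMercator:
    """Local transverse-Mercator projection on the WGS84 ellipsoid.

    Uses the Krüger series (third order in the third flattening ``n``),
    accurate to well under a decimetre within a few degrees of the central
    meridian — far below the GPS error of the tracking data.  The projection
    is centred so that ``(lon0, lat0)`` maps to ``(0, 0)``; x grows east,
    y grows north, both in metres.
    """

    lon0: float
    lat0: float

    def __post_init__(self) -> None:
        f = _WGS84_F
        self._e = math.sqrt(f * (2.0 - f))
        n = f / (2.0 - f)
        self._n = n
        self._A = _WGS84_A / (1.0 + n) * (1.0 + n**2 / 4.0 + n**4 / 64.0)
        self._alpha = (
            n / 2.0 - 2.0 * n**2 / 3.0 + 5.0 * n**3 / 16.0,
            13.0 * n**2 / 48.0 - 3.0 * n**3 / 5.0,
            61.0 * n**3 / 240.0,
        )
        self._beta = (
            n / 2.0 - 2.0 * n**2 / 3.0 + 37.0 * n**3 / 96.0,
            n**2 / 48.0 + n**3 / 15.0,
            17.0 * n**3 / 480.0,
        )
        self._x0, self._y0 = self._forward_raw(self.lon0, self.lat0)

    # -- raw Krüger forward/inverse (no false origin) ----------------------

    def _forward_raw(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        e = self._e
        lam = np.radians(lon - self.lon0)
        phi = np.radians(lat)
        s = np.sin(phi)
        # conformal latitude
        t = np.sinh(np.arctanh(s) - e * np.arctanh(e * s))
        xi = np.arctan2(t, np.cos(lam))
        eta = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))
        xi_s, eta_s = xi.copy(), eta.copy()
        for j, a in enumerate(self._alpha, start=1):
            xi_s += a * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
            eta_s += a * np.cos(2 * j * xi) * np.sinh(2 * j * eta)
        return self._A * eta_s, self._A * xi_s

    def _inverse_raw(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        e = self._e
        xi = y / self._A
        eta = x / self._A
        xi_p, eta_p = xi.copy(), eta.copy()
        for j, b in enumerate(self._beta, start=1):
            xi_p -= b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
            eta_p -= b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)
        lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
        tau = np.sin(xi_p) / np.hypot(np.sinh(eta_p), np.cos(xi_p))
        # invert the conformal latitude by fixed point on sin(phi)
        psi = np.arcsinh(tau)
        s = np.tanh(psi)
        for _ in range(8):
            s = np.tanh(psi + e * np.arctanh(e * s))
        phi = np.arcsin(np.clip(s, -1.0, 1.0))
        return np.degrees(lam) + self.lon0, np.degrees(phi)

    # -- public API --------------------------------------------------------

    def forward(self, lon, lat):
        """Project geographic degrees to planar metres (x east, y north)."""
        lat_arr = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat_arr) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
        x, y = self._forward_raw(lon, lat)
        return x - self._x0, y - self._y0

    def inverse(self, x, y):
        """Back-project planar metres to geographic degrees."""
        return self._inverse_raw(
            np.asarray(x, dtype=float) + self._x0,
            np.asarray(y, dtype=float) + self._y0,
        )


def project_coords(lon, lat, projection: TransverseMercator):
    """Project longitude/latitude (degrees) to planar ``(x, y)`` metres."""
    return projection.forward(lon, lat)


# ---------------------------------------------------------------------------
# DEM
# ---------------------------------------------------------------------------


@dataclass
class DemGrid:
    """A gridded digital elevation model with optional derived layers.

    ``elevation`` is row-major with row 0 at the *north* edge (the ESRI ASCII
    convention); ``xll``/``yll`` give the lower-left (south-west) corner of
    the grid.  ``slope`` (degrees) and ``aspect`` (compass degrees, direction
    of steepest ascent, 0 = north, clockwise) are ``None`` until derived by
    :func:`groupcot.energetics.compute_slope_aspect`.
    """

    xll: float
    yll: float
    cell_size: float
    elevation: np.ndarray
    slope: np.ndarray | None = None
    aspect: np.ndarray | None = None
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        self.elevation = np.asarray(self.elevation, dtype=float)

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    def cell_index(self, x, y):
        """Row/column of the cell containing each position.

        Half-open cell bounds; positions outside the grid are clamped to the
        nearest edge cell (tracks may briefly leave a synthetic grid).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xll) / self.cell_size).astype(int)
        row_from_south = np.floor((y - self.yll) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_south
        return (
            np.clip(row, 0, self.n_rows - 1),
            np.clip(col, 0, self.n_cols - 1),
        )


def read_dem(path) -> DemGrid:
    """Load an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"missing DEM header field: {key}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if len(rows) != nrows or any(len(r) != ncols for r in rows):
        raise FormatError("DEM data block does not match ncols/nrows header")
    nodata = header.get("nodata_value", -9999.0)
    elev = np.array(rows, dtype=float)
    elev[elev == nodata] = np.nan
    return DemGrid(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell_size=header["cellsize"],
        elevation=elev,
        nodata=nodata,
    )


def write_dem(dem: DemGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {dem.n_cols}\n")
        fh.write(f"nrows {dem.n_rows}\n")
        fh.write(f"xllcorner {float(dem.xll)!r}\n")
        fh.write(f"yllcorner {float(dem.yll)!r}\n")
        fh.write(f"cellsize {float(dem.cell_size)!r}\n")
        fh.write(f"nodata_value {float(dem.nodata)!r}\n")
        elev = np.where(np.isnan(dem.elevation), dem.nodata, dem.elevation)
        for row in elev:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# fix tables
# ---------------------------------------------------------------------------


@dataclass
class FixDialect:
    """Column mapping of the fix-table CSV dialect."""

    individual: str = COL_ID
    timestamp: str = COL_TIME
    lon: str = COL_LON
    lat: str = COL_LAT
    x: str = COL_X
    y: str = COL_Y
    regime: str = COL_REGIME


def read_fixes(
    path,
    dialect: FixDialect | None = None,
    projection: TransverseMercator | None = None,
) -> pd.DataFrame:
    """Read a fix table, returning the canonical planar fix frame.

    Coordinates may be geographic (``location-long``/``location-lat``; a
    projection is then required, or one is built centred on the data extent)
    or already planar (``x``/``y`` metres).  Rows with unparseable
    coordinates are dropped with a logged count; duplicate
    ``(individual, timestamp)`` rows keep the first occurrence.
    """
    dialect = dialect or FixDialect()
    raw = pd.read_csv(path)
    for col in (dialect.individual, dialect.timestamp):
        if col not in raw.columns:
            raise FormatError(f"missing mandatory column: {col}")
    planar = dialect.x in raw.columns and dialect.y in raw.columns
    geographic = dialect.lon in raw.columns and dialect.lat in raw.columns
    if not planar and not geographic:
        raise FormatError(
            f"missing mandatory column: {dialect.lon}/{dialect.lat} "
            f"or {dialect.x}/{dialect.y}"
        )

    out = pd.DataFrame(
        {
            "individual": raw[dialect.individual].astype(str),
            "time": pd.to_datetime(raw[dialect.timestamp], errors="coerce"),
        }
    )
    if planar:
        out["x"] = pd.to_numeric(raw[dialect.x], errors="coerce")
        out["y"] = pd.to_numeric(raw[dialect.y], errors="coerce")
    else:
        lon = pd.to_numeric(raw[dialect.lon], errors="coerce")
        lat = pd.to_numeric(raw[dialect.lat], errors="coerce")
        if projection is None:
            projection = TransverseMercator(
                float(lon.mean()), float(lat.mean())
            )
        x, y = projection.forward(lon.to_numpy(), lat.to_numpy())
        out["x"] = x
        out["y"] = y
    out["regime"] = (
        raw[dialect.regime].astype(str)
        if dialect.regime in raw.columns
        else "hires"
    )

    bad = out[["time", "x", "y"]].isna().any(axis=1)
    if bad.any():
        logger.warning("dropped %d rows with unparseable fields", int(bad.sum()))
        out = out[~bad]
    n_before = len(out)
    out = out.sort_values(["individual", "time"], kind="stable")
    out = out.drop_duplicates(subset=["individual", "time"], keep="first")
    if len(out) < n_before:
        logger.warning(
            "dropped %d duplicate (individual, timestamp) rows",
            n_before - len(out),
        )
    return out.reset_index(drop=True)


def write_fixes(fixes: pd.DataFrame, path, dialect: FixDialect | None = None) -> None:
    """Write the canonical fix frame in the planar CSV dialect."""
    dialect = dialect or FixDialect()
    out = pd.DataFrame(
        {
            dialect.individual: fixes["individual"],
            dialect.timestamp: fixes["time"].dt.strftime("%Y-%m-%d %H:%M:%S"),
            dialect.x: fixes["x"],
            dialect.y: fixes["y"],
            dialect.regime: fixes["regime"],
        }
    )
    out.to_csv(path, index=False)
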