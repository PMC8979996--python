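"""Georeferenced scalar grids on the WGS84 geographic graticule.

A :class:`GeoGrid` is the single in-memory carrier for every raster the
pipeline touches: diffuse attenuation (``kd490``, ``kdpar``), irradiance
(``par0``, ``ez``), bathymetric depth (``depth``, positive metres down),
percent of surface PAR (``percent_par``) and boolean zone masks (``mask``).
Missing cells are ``NaN`` in memory; the ``nodata`` attribute is only the
sentinel used on disk.

Grids are always stored north-up: row 0 is the northernmost row.  Two grids
are *aligned* when transform, shape and CRS are identical; arithmetic between
grids is only meaningful when they are aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

WGS84 = "EPSG:4326"

#: Authalic Earth radius in km, used for all geodesic lengths and areas.
EARTH_RADIUS_KM = 6371.0088

ROLES = frozenset(
    {"kd490", "par0", "kdpar", "depth", "ez", "percent_par", "mask"}
)


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference of a north-up regular lon/lat grid.

    ``lon0``/``lat0`` are the *outer corner* of the (0, 0) cell — the west
    edge of the first column and the north edge of the first row.  Cell
    centers therefore sit at ``lon0 + (j + 0.5) * dlon`` and
    ``lat0 - (i + 0.5) * dlat``.
    """

    lon0: float
    lat0: float
    dlon: float
    dlat: float

    def __post_init__(self) -> None:
        if not (self.dlon > 0 and self.dlat > 0):
            raise ValueError("cell width and height must be positive")

    # -- coordinate helpers -------------------------------------------------
    def lon_centers(self, ncols: int) -> np.ndarray:
        return self.lon0 + (np.arange(ncols) + 0.5) * self.dlon

    def lat_centers(self, nrows: int) -> np.ndarray:
        return self.lat0 - (np.arange(nrows) + 0.5) * self.dlat

    def lon_edges(self, ncols: int) -> np.ndarray:
        return self.lon0 + np.arange(ncols + 1) * self.dlon

    def lat_edges(self, nrows: int) -> np.ndarray:
        return self.lat0 - np.arange(nrows + 1) * self.dlat

    def rowcol(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Integer cell indices containing the given points (half-open cells)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon0) / self.dlon).astype(np.int64)
        row = np.floor((self.lat0 - lat) / self.dlat).astype(np.int64)
        return row, col

    def fractional_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Continuous (row, col) index of points relative to *cell centers*."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        fc = (lon - self.lon0) / self.dlon - 0.5
        fr = (self.lat0 - lat) / self.dlat - 0.5
        return fr, fc

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer bounds for a grid of ``shape``."""
        nrows, ncols = shape
        return (
            self.lon0,
            self.lat0 - nrows * self.dlat,
            self.lon0 + ncols * self.dlon,
            self.lat0,
        )


@dataclass
class GeoGrid:
    """A single-band georeferenced field. ``NaN`` marks missing cells."""

    values: np.ndarray
    transform: GridTransform
    role: str = "mask"
    crs: str = WGS84
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("GeoGrid values must be 2-D")
        if self.role not in ROLES:
            raise ValueError(f"unknown grid role {self.role!r}; expected one of {sorted(ROLES)}")

    # -- basic geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.transform.bounds(self.shape)

    def lon_centers(self) -> np.ndarray:
        return self.transform.lon_centers(self.shape[1])

    def lat_centers(self) -> np.ndarray:
        return self.transform.lat_centers(self.shape[0])

    # -- alignment ----------------------------------------------------------
    def aligned_with(self, other: "GeoGrid", *, tol: float = 1e-9) -> bool:
        if self.shape != other.shape or self.crs != other.crs:
            return False
        a, b = self.transform, other.transform
        return (
            abs(a.lon0 - b.lon0) <= tol
            and abs(a.lat0 - b.lat0) <= tol
            and abs(a.dlon - b.dlon) <= tol
            and abs(a.dlat - b.dlat) <= tol
        )

    def like(self, values: np.ndarray, role: str | None = None) -> "GeoGrid":
        """A new grid sharing this grid's georeference."""
        return GeoGrid(
            values=np.asarray(values, dtype=np.float64),
            transform=self.transform,
            role=role or self.role,
            crs=self.crs,
            nodata=self.nodata,
        )

    # -- value checks -------------------------------------------------------
    def check(self) -> None:
        """Raise if the role-specific value invariants are violated."""
        v = self.values[self.valid]
        if v.size == 0:
            return
        if self.role in ("kd490", "par0") and not np.all(v > 0):
            raise ValueError(f"role={self.role} requires strictly positive values")
        if self.role == "depth" and not np.all(v >= 0):
            raise ValueError("role=depth requires non-negative (positive-down) values")
        if self.role == "percent_par" and not (np.all(v >= 0) & np.all(v <= 100)):
            raise ValueError("role=percent_par requires values in [0, 100]")

    def sample_nearest(self, lon, lat) -> np.ndarray:
        """Nearest-cell values at points; NaN outside the grid."""
        row, col = self.transform.rowcol(lon, lat)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        out = np.full(row.shape, np.nan)
        inside = (row >= 0) & (row < self.shape[0]) & (col >= 0) & (col < self.shape[1])
        out[inside] = self.values[row[inside], col[inside]]
        return out


def require_aligned(*grids: GeoGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.aligned_with(g):
            raise ValueError(
                "grids are not aligned (transform/shape/CRS differ); "
                "resample onto a common template first"
            )


@dataclass
class GridStack:
    """An ordered set of aligned grids of one role (e.g. a daily time series)."""

    grids: Sequence[GeoGrid]
    timestamps: Sequence | None = None

    def __post_init__(self) -> None:
        if len(self.grids) == 0:
            raise ValueError("GridStack requires at least one grid")
        roles = {g.role for g in self.grids}
        if len(roles) > 1:
            raise ValueError(f"GridStack members must share one role, got {sorted(roles)}")
        require_aligned(*self.grids)
        if self.timestamps is not None and len(self.timestamps) != len(self.grids):
            raise ValueError("timestamps length must match number of grids")

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self):
        return iter(self.grids)

    @property
    def role(self) -> str:
        return self.grids[0].role
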