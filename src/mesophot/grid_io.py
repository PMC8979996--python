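"""Raster input/output, temporal averaging and grid harmonization.

GeoTIFF is the on-disk format for every raster artifact (single band,
float32, nodata tagged via GDAL_NODATA, georeference via the GeoTIFF
ModelPixelScale/ModelTiepoint tags).  NetCDF files with regular CF-style
``lon``/``lat`` coordinate variables are accepted on input.

The satellite fields (~4 km) and the bathymetry (~100 m) arrive on
different grids; :func:`resample_to` brings them onto one template before
any optics is applied — bilinear by default, with a nearest-valid coastal
fallback where the 2x2 bilinear support is incomplete (shoreline cells of
ocean-colour products are frequently masked).
"""

from __future__ import annotations

import warnings
from os import PathLike
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .grid import GeoGrid, GridStack, GridTransform, WGS84, require_aligned

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# Minimal GeoKeyDirectory: geographic model, pixel-is-area, EPSG:4326.
_WGS84_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)

_NETCDF_SUFFIXES = {".nc", ".nc4", ".cdf", ".netcdf"}


def _is_regular(coord: np.ndarray, *, rtol: float = 1e-5) -> bool:
    d = np.diff(coord)
    if d.size == 0:
        return True
    return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))


def _depth_from_values(values: np.ndarray) -> np.ndarray:
    """Normalize a depth raster to positive metres down.

    Elevation rasters (sea floor below datum as negative values) are
    recognized by a negative median over valid cells (robust to high land
    elevations) and negated; any cell left negative after the convention
    is applied (land above datum) becomes nodata.
    """
    valid = np.isfinite(values)
    if valid.any() and np.nanmedian(values) < 0:
        values = -values
    values = values.copy()
    values[np.isfinite(values) & (values < 0)] = np.nan
    return values


def read_grid(
    path: str | PathLike,
    role: str,
    *,
    variable: str | None = None,
    band: int | None = None,
) -> GeoGrid:
    """Read a single-band GeoTIFF or a NetCDF variable as a :class:`GeoGrid`.

    Nodata cells become NaN.  Depth rasters supplied as negative elevation
    are converted to positive depth in metres.  Multi-band rasters require
    an explicit ``band`` (0-based); NetCDF files with several 2-D variables
    require ``variable``.
    """
    path = Path(path)
    if path.suffix.lower() in _NETCDF_SUFFIXES:
        values, transform = _read_netcdf(path, variable)
    else:
        values, transform = _read_geotiff(path, band)
    if role == "depth":
        values = _depth_from_values(values)
    return GeoGrid(values=values, transform=transform, role=role)


def _read_geotiff(path: Path, band: int | None) -> tuple[np.ndarray, GridTransform]:
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        if len(pages) > 1 and band is None:
            raise ValueError(
                f"{path.name}: multi-band raster ({len(pages)} bands); pass band="
            )
        page = pages[band or 0]
        if page.samplesperpixel > 1:
            raise ValueError(f"{path.name}: multi-sample pages are not supported")
        data = page.asarray().astype(np.float64)
        tags = page.tags
        scale = tags.valueof(_MODEL_PIXEL_SCALE)
        tiepoint = tags.valueof(_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise ValueError(f"{path.name}: missing GeoTIFF georeference tags")
        dlon, dlat = float(scale[0]), float(scale[1])
        i, j = float(tiepoint[0]), float(tiepoint[1])
        lon0 = float(tiepoint[3]) - i * dlon
        lat0 = float(tiepoint[4]) + j * dlat
        nodata_tag = tags.valueof(_GDAL_NODATA)
        if nodata_tag is not None:
            nodata = float(str(nodata_tag).strip("\x00 "))
            if np.isnan(nodata):
                pass  # already NaN-coded
            else:
                data[data == nodata] = np.nan
    return data, GridTransform(lon0=lon0, lat0=lat0, dlon=dlon, dlat=dlat)


def _read_netcdf(path: Path, variable: str | None) -> tuple[np.ndarray, GridTransform]:
    import xarray as xr

    with xr.open_dataset(path) as ds:
        lon_name = next((n for n in ("lon", "longitude", "x") if n in ds.coords), None)
        lat_name = next((n for n in ("lat", "latitude", "y") if n in ds.coords), None)
        if lon_name is None or lat_name is None:
            raise ValueError(f"{path.name}: no lon/lat coordinate variables found")
        if variable is None:
            candidates = [
                n for n, v in ds.data_vars.items()
                if set(v.dims) == {ds[lat_name].dims[0], ds[lon_name].dims[0]}
            ]
            if len(candidates) != 1:
                raise ValueError(
                    f"{path.name}: pass variable=; candidates are {candidates}"
                )
            variable = candidates[0]
        da = ds[variable].transpose(ds[lat_name].dims[0], ds[lon_name].dims[0])
        lon = np.asarray(ds[lon_name], dtype=float)
        lat = np.asarray(ds[lat_name], dtype=float)
        if not _is_regular(lon) or not _is_regular(lat):
            raise ValueError(f"{path.name}: non-regular grid (uneven lon/lat spacing)")
        values = np.asarray(da, dtype=np.float64)
        if lat.size > 1 and lat[1] > lat[0]:  # south-up file: flip to north-up
            values = values[::-1]
            lat = lat[::-1]
        dlon = float(abs(lon[1] - lon[0])) if lon.size > 1 else 1.0
        dlat = float(abs(lat[0] - lat[1])) if lat.size > 1 else 1.0
        transform = GridTransform(
            lon0=float(lon[0]) - dlon / 2,
            lat0=float(lat[0]) + dlat / 2,
            dlon=dlon,
            dlat=dlat,
        )
    return values, transform


def write_grid(grid: GeoGrid, path: str | PathLike) -> None:
    """Write a grid as a single-band float32 GeoTIFF with nodata tagged.

    ``read_grid(write_grid(g))`` reproduces values, transform and nodata
    mask bit-for-bit for float32-representable values.
    """
    path = Path(path)
    t = grid.transform
    data = grid.values.astype(np.float32)
    data = np.where(np.isfinite(data), data, np.float32(grid.nodata))
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (t.dlon, t.dlat, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.lon0, t.lat0, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS),
        (_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, data, photometric="minisblack", extratags=extratags)


def temporal_mean(stack: GridStack) -> GeoGrid:
    """Per-cell arithmetic mean over a stack, missing observations excluded.

    A cell valid in zero members is nodata in the output.  This is the
    climatology step: a multi-year mean of daily (or pre-averaged) fields.
    """
    cube = np.stack([g.values for g in stack.grids])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(cube, axis=0)
    return stack.grids[0].like(mean)


def resample_to(
    source: GeoGrid,
    template: GeoGrid,
    method: str = "bilinear",
    *,
    fallback_radius: float = 2.0,
) -> GeoGrid:
    """Resample ``source`` onto ``template``'s grid.

    ``bilinear`` interpolates from the four surrounding source-cell centers
    wherever all contributing cells are valid; where support is incomplete
    (coastline, source nodata, grid edge) the nearest valid source cell
    within ``fallback_radius`` source-cell widths is used instead, and cells
    beyond that radius are nodata.  ``nearest`` takes the enclosing source
    cell with no fallback, so resampling a grid onto itself is the identity.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    sw, ss, se, sn = source.bounds
    tw, ts, te, tn = template.bounds
    if te <= sw or tw >= se or tn <= ss or ts >= sn:
        raise ValueError("source and template extents are disjoint")

    lons = template.lon_centers()
    lats = template.lat_centers()
    fr_1d, _ = source.transform.fractional_index(np.full_like(lats, source.bounds[0]), lats)
    _, fc_1d = source.transform.fractional_index(lons, np.full_like(lons, source.bounds[3]))
    fr = np.broadcast_to(fr_1d[:, None], (lats.size, lons.size))
    fc = np.broadcast_to(fc_1d[None, :], (lats.size, lons.size))

    src = source.values
    nrows, ncols = src.shape
    valid = np.isfinite(src)

    if method == "nearest":
        ir = np.round(fr).astype(np.int64)
        jc = np.round(fc).astype(np.int64)
        inside = (ir >= 0) & (ir < nrows) & (jc >= 0) & (jc < ncols)
        out = np.full(fr.shape, np.nan)
        out[inside] = src[ir[inside], jc[inside]]
        return template.like(out, role=source.role)

    i0 = np.floor(fr).astype(np.int64)
    j0 = np.floor(fc).astype(np.int64)
    wy = fr - i0
    wx = fc - j0
    out = np.zeros(fr.shape)
    supported = np.ones(fr.shape, dtype=bool)
    for di, dj, w in (
        (0, 0, (1 - wy) * (1 - wx)),
        (0, 1, (1 - wy) * wx),
        (1, 0, wy * (1 - wx)),
        (1, 1, wy * wx),
    ):
        ii = np.clip(i0 + di, 0, nrows - 1)
        jj = np.clip(j0 + dj, 0, ncols - 1)
        corner_ok = (
            (i0 + di >= 0) & (i0 + di < nrows)
            & (j0 + dj >= 0) & (j0 + dj < ncols)
            & valid[ii, jj]
        )
        needed = w > 0
        supported &= corner_ok | ~needed
        out += np.where(needed & corner_ok, w * src[ii, jj], 0.0)
    out[~supported] = np.nan

    # nearest-valid coastal fallback for unsupported template cells
    if (~supported).any() and valid.any():
        inds = ndimage.distance_transform_edt(
            ~valid, return_distances=False, return_indices=True
        )
        ir = np.clip(np.round(fr).astype(np.int64), 0, nrows - 1)
        jc = np.clip(np.round(fc).astype(np.int64), 0, ncols - 1)
        iv = inds[0][ir, jc]
        jv = inds[1][ir, jc]
        dist = np.hypot(fr - iv, fc - jv)
        use = ~supported & (dist <= fallback_radius)
        out[use] = src[iv[use], jv[use]]
    return template.like(out, role=source.role)
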