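"""Delineate the mesophotic zone and account its area per sub-region.

The zone is the seabed that is (i) at or below the 30 m upper depth bound
and (ii) still receiving at least the minimum photon dose ``e_min``
(0.0001 mol photons m^-2 day^-1 by default) — i.e. between the fixed
depth bound and the lower isolume.  Both bounds are inclusive.

Areas are computed on the raster mask with exact spherical cell areas
(authalic radius R = 6371.0088 km), and sub-region membership uses the
cell-center rule, so every km^2 in a report is analytically reproducible.
Vectorized polygons are provided for export and cartography.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape
from shapely.ops import unary_union

from .grid import EARTH_RADIUS_KM, GeoGrid, require_aligned

logger = logging.getLogger(__name__)

MSFD_SUBREGIONS = (
    "Western Mediterranean Sea",
    "Adriatic Sea",
    "Ionian and Central Mediterranean Sea",
    "Aegean-Levantine Sea",
)


@dataclass
class SubRegion:
    """A named reporting polygon (e.g. an MSFD sub-region)."""

    name: str
    polygon: Polygon | MultiPolygon
    reference_area_km2: float | None = None

    def __post_init__(self) -> None:
        if self.polygon.is_empty:
            raise ValueError(f"sub-region {self.name!r} has an empty polygon")


@dataclass
class MesophoticZone:
    """Boolean zone mask plus the grids and thresholds it was derived from.

    ``mask.values`` holds 1.0 (mesophotic), 0.0 (not), NaN (undetermined:
    invalid in depth or irradiance).  The depth and irradiance grids are
    retained so border cells can later be attributed to the constraint that
    excludes their neighbour (depth bound vs light bound).
    """

    mask: GeoGrid
    depth: GeoGrid
    ez: GeoGrid
    upper_depth: float = 30.0
    e_min: float = 0.0001

    @property
    def true_mask(self) -> np.ndarray:
        return self.mask.values == 1.0

    @property
    def n_cells(self) -> int:
        return int(self.true_mask.sum())

    def polygons(self) -> MultiPolygon:
        return polygonize(self)


def delineate(
    depth: GeoGrid,
    ez: GeoGrid,
    upper_depth: float = 30.0,
    e_min: float = 0.0001,
) -> MesophoticZone:
    """Mask the seabed under mesophotic conditions.

    A cell is mesophotic iff depth >= ``upper_depth`` AND irradiance >=
    ``e_min`` (both inclusive) and both inputs are valid there; cells
    invalid in either input are nodata and counted in the log.
    """
    require_aligned(depth, ez)
    valid = depth.valid & ez.valid
    inside = (depth.values >= upper_depth) & (ez.values >= e_min)
    values = np.where(valid, inside.astype(np.float64), np.nan)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("delineate: %d cell(s) undetermined (invalid depth or irradiance)",
                    n_excluded)
    mask = depth.like(values, role="mask")
    return MesophoticZone(mask=mask, depth=depth, ez=ez,
                          upper_depth=upper_depth, e_min=e_min)


def polygonize(zone: MesophoticZone) -> MultiPolygon:
    """Dissolve the true cells' rectangular footprints into polygons.

    Holes (enclosed non-mesophotic cells) are preserved.  Row runs of
    consecutive true cells are merged into single rectangles before the
    union, which keeps the geometry count manageable on large masks.
    """
    t = zone.mask.transform
    true = zone.true_mask
    if not true.any():
        logger.warning("polygonize: empty mask -> empty multipolygon")
        return MultiPolygon([])
    rects = []
    lon_edges = t.lon_edges(true.shape[1])
    lat_edges = t.lat_edges(true.shape[0])
    for i in range(true.shape[0]):
        row = true[i]
        if not row.any():
            continue
        # run-length encode the row
        edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.int8), [0]))))
        for j0, j1 in zip(edges[::2], edges[1::2]):
            rects.append(box(lon_edges[j0], lat_edges[i + 1], lon_edges[j1], lat_edges[i]))
    merged = unary_union(rects)
    if isinstance(merged, Polygon):
        merged = MultiPolygon([merged])
    return merged


def cell_areas(template: GeoGrid) -> GeoGrid:
    """Spherical surface area of every cell, in km^2.

    (pi/180) * R^2 * |dlon| * |sin(lat_top) - sin(lat_bottom)| — constant
    along rows and shrinking toward the poles.
    """
    t = template.transform
    lat_edges = np.radians(t.lat_edges(template.shape[0]))
    band = np.abs(np.diff(np.sin(lat_edges)))  # per row
    row_area = math.radians(t.dlon) * EARTH_RADIUS_KM**2 * band
    values = np.broadcast_to(row_area[:, None], template.shape).copy()
    return template.like(values, role="mask")


def spherical_area_km2(geom: Polygon | MultiPolygon) -> float:
    """Spherical area of a lon/lat polygon whose edges are linear in lon/lat.

    Exact for grid-aligned polygons (the output of :func:`polygonize`);
    for slanted edges the latitude is integrated along the lon/lat-linear
    edge, which matches the rectangle decomposition used for rasters.
    """
    def ring_area(coords) -> float:
        lam = np.radians([c[0] for c in coords])
        phi = np.radians([c[1] for c in coords])
        total = 0.0
        for k in range(len(lam) - 1):
            dlam = lam[k + 1] - lam[k]
            dphi = phi[k + 1] - phi[k]
            if dlam == 0.0:
                continue
            if dphi == 0.0:
                total += math.sin(phi[k]) * dlam
            else:  # integral of sin(phi(lambda)) d lambda for linear phi(lambda)
                total += (math.cos(phi[k]) - math.cos(phi[k + 1])) * dlam / dphi
        return abs(total) * EARTH_RADIUS_KM**2

    polys = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    area = 0.0
    for p in polys:
        area += ring_area(p.exterior.coords)
        for hole in p.interiors:
            area -= ring_area(hole.coords)
    return area


def area_report(
    zone: MesophoticZone,
    subregions: list[SubRegion],
    template: GeoGrid | None = None,
) -> pd.DataFrame:
    """Mesophotic area per sub-region, plus a pooled basin row.

    Cell membership is by cell-center point-in-polygon.  Percent is taken
    against the sub-region's own cell-center area unless a published
    ``reference_area_km2`` is supplied.  Columns: region, mesophotic_km2,
    region_km2, percent.
    """
    template = template or zone.mask
    areas = cell_areas(template).values
    true = zone.true_mask
    lons = template.lon_centers()
    lats = template.lat_centers()
    lon_g, lat_g = np.meshgrid(lons, lats)

    rows = []
    total_meso = total_region = 0.0
    for sr in subregions:
        inside = shapely.contains_xy(sr.polygon, lon_g.ravel(), lat_g.ravel())
        inside = inside.reshape(template.shape)
        meso_km2 = float(areas[inside & true].sum())
        region_km2 = (
            sr.reference_area_km2
            if sr.reference_area_km2 is not None
            else float(areas[inside].sum())
        )
        if not inside.any():
            logger.warning("area_report: sub-region %r overlaps no grid cells", sr.name)
        pct = 100.0 * meso_km2 / region_km2 if region_km2 > 0 else np.nan
        rows.append((sr.name, meso_km2, region_km2, pct))
        total_meso += meso_km2
        total_region += region_km2
    basin_pct = 100.0 * total_meso / total_region if total_region > 0 else np.nan
    rows.append(("Basin", total_meso, total_region, basin_pct))
    return pd.DataFrame(rows, columns=["region", "mesophotic_km2", "region_km2", "percent"])


# ---------------------------------------------------------------------------
# GeoJSON plumbing for sub-regions and the zone polygons

def read_subregions(path: str | PathLike) -> list[SubRegion]:
    """Load sub-regions from a GeoJSON FeatureCollection with a ``name`` property."""
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        name = props.get("name") or props.get("NAME")
        if name is None:
            raise ValueError("sub-region feature missing a 'name' property")
        out.append(SubRegion(
            name=name,
            polygon=shape(feat["geometry"]),
            reference_area_km2=props.get("reference_area_km2"),
        ))
    return out


def write_subregions(subregions: list[SubRegion], path: str | PathLike) -> None:
    feats = []
    for sr in subregions:
        props = {"name": sr.name}
        if sr.reference_area_km2 is not None:
            props["reference_area_km2"] = sr.reference_area_km2
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(sr.polygon)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_zone_geojson(zone: MesophoticZone, path: str | PathLike) -> None:
    geom = polygonize(zone)
    feature = {
        "type": "Feature",
        "properties": {
            "upper_depth_m": zone.upper_depth,
            "e_min": zone.e_min,
            "area_km2": spherical_area_km2(geom),
        },
        "geometry": mapping(geom),
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)
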