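"""Filter and classify benthic occurrence records against the light model.

Literature records of mesophotic assemblages arrive as a CSV of
georeferenced points in four groups (generic assemblages, coralligenous,
rhodolith beds, or both).  They pass through a fixed exclusion chain —
land, outside the satellite extent, deeper than 500 m — and the survivors
are classified *above* / *within* / *below* the mesophotic zone from the
bathymetry and the modelled seabed irradiance, providing an independent
ground-truthing of the delineation.
"""

from __future__ import annotations

import logging
from os import PathLike

import numpy as np
import pandas as pd

from .grid import GeoGrid, require_aligned

logger = logging.getLogger(__name__)

GROUPS = (
    "Generic assemblages",
    "Coralligenous",
    "Rhodolith beds",
    "Coralligenous and rhodolith",
)

STATUSES = ("excluded_land", "excluded_extent", "excluded_deep", "above", "within", "below")


def load_records(path: str | PathLike) -> pd.DataFrame:
    """Load the occurrence CSV (columns id, lon, lat, group[, depth_m, source]).

    Unknown group labels and out-of-range coordinates are rejected with the
    offending row numbers.
    """
    df = pd.read_csv(path)
    missing = {"id", "lon", "lat", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing column(s): {sorted(missing)}")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad_coord = ~np.isfinite(lon) | ~np.isfinite(lat)
    if bad_coord.any():
        raise ValueError(f"unparseable coordinates at rows {list(df.index[bad_coord])}")
    out_lon = (lon < -180) | (lon > 180)
    if out_lon.any():
        raise ValueError(f"longitude out of range at rows {list(df.index[out_lon])}")
    out_lat = (lat < -90) | (lat > 90)
    if out_lat.any():
        raise ValueError(f"latitude out of range at rows {list(df.index[out_lat])}")
    unknown = ~df["group"].isin(GROUPS)
    if unknown.any():
        raise ValueError(
            f"unknown assemblage group at rows {list(df.index[unknown])}; "
            f"allowed: {list(GROUPS)}"
        )
    df = df.copy()
    df["lon"] = lon
    df["lat"] = lat
    return df


def filter_records(
    records: pd.DataFrame,
    depth: GeoGrid,
    kd490: GeoGrid,
    par0: GeoGrid | None = None,
    max_depth: float = 500.0,
) -> pd.DataFrame:
    """Apply the exclusion chain; survivors keep status ``"candidate"``.

    Precedence: (1) ``excluded_land`` where the bathymetry marks land
    (nodata on the marine grid, or depth <= 0); (2) ``excluded_extent``
    where the satellite field(s) are nodata — the intersection of Kd490 and
    surface PAR when both are given — or the point falls off the grid
    entirely; (3) ``excluded_deep`` beyond ``max_depth``.  Counts per
    status are logged.
    """
    require_aligned(depth, kd490, *(g for g in (par0,) if g is not None))
    df = records.copy()
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    row, col = depth.transform.rowcol(lon, lat)
    inside = (
        (row >= 0) & (row < depth.shape[0]) & (col >= 0) & (col < depth.shape[1])
    )
    d = np.full(len(df), np.nan)
    d[inside] = depth.values[row[inside], col[inside]]
    sat_ok = np.zeros(len(df), dtype=bool)
    kd = np.full(len(df), np.nan)
    kd[inside] = kd490.values[row[inside], col[inside]]
    sat_ok[inside] = np.isfinite(kd[inside])
    if par0 is not None:
        p0 = np.full(len(df), np.nan)
        p0[inside] = par0.values[row[inside], col[inside]]
        sat_ok &= np.isfinite(p0)

    status = np.full(len(df), "candidate", dtype=object)
    land = inside & (~np.isfinite(d) | (d <= 0))
    status[land] = "excluded_land"
    extent = (status == "candidate") & (~inside | ~sat_ok)
    status[extent] = "excluded_extent"
    deep = (status == "candidate") & (d > max_depth)
    status[deep] = "excluded_deep"

    df["depth"] = d
    df["status"] = status
    for s in ("excluded_land", "excluded_extent", "excluded_deep", "candidate"):
        logger.info("filter_records: %s = %d", s, int((status == s).sum()))
    return df


def classify_records(
    records: pd.DataFrame,
    depth: GeoGrid,
    ez: GeoGrid,
    upper_depth: float = 30.0,
    e_min: float = 0.0001,
) -> pd.DataFrame:
    """Assign above/within/below to the filter survivors.

    Depth comes from the bathymetry grid unless a finite ``depth_m`` column
    is present (then preferred and flagged in ``depth_source``).  A record
    is *above* when shallower than the upper bound, *within* when at or
    below it and still receiving at least ``e_min``, *below* otherwise —
    the same inclusive conventions as the zone mask.
    """
    require_aligned(depth, ez)
    df = records.copy()
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    grid_depth = depth.sample_nearest(lon, lat)
    irr = ez.sample_nearest(lon, lat)

    d = grid_depth.copy()
    source = np.full(len(df), "bathymetry", dtype=object)
    if "depth_m" in df.columns:
        own = pd.to_numeric(df["depth_m"], errors="coerce").to_numpy()
        use = np.isfinite(own)
        d[use] = own[use]
        source[use] = "record"
        if use.any():
            logger.info("classify_records: %d record depth(s) taken from the CSV", int(use.sum()))

    cand = (df["status"] == "candidate").to_numpy() if "status" in df.columns \
        else np.ones(len(df), dtype=bool)
    status = df["status"].to_numpy(dtype=object) if "status" in df.columns \
        else np.full(len(df), "candidate", dtype=object)
    above = cand & (d < upper_depth)
    within = cand & (d >= upper_depth) & (irr >= e_min)
    below = cand & (d >= upper_depth) & ~(irr >= e_min)
    status[above] = "above"
    status[within] = "within"
    status[below] = "below"

    df["depth"] = d
    df["depth_source"] = source
    df["irradiance"] = irr
    df["status"] = status
    return df


def validation_report(enriched: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts/percentages per status, and per-group counts with depth ranges.

    Percentages for the above/within/below classes are taken against the
    post-filter total; exclusion classes are reported against the input
    total.  Depth ranges (min, median, max) cover non-excluded records.
    """
    if enriched.empty:
        logger.warning("validation_report: no records")
        empty = pd.DataFrame()
        return empty, empty
    n_total = len(enriched)
    counts = enriched["status"].value_counts()
    classified = ("above", "within", "below")
    n_classified = int(sum(counts.get(s, 0) for s in classified))
    rows = []
    for s in STATUSES:
        n = int(counts.get(s, 0))
        base = n_classified if s in classified else n_total
        rows.append({
            "status": s,
            "count": n,
            "percent": 100.0 * n / base if base else np.nan,
        })
    status_table = pd.DataFrame(rows)

    kept = enriched[enriched["status"].isin(classified)]
    group_rows = []
    for g, sub in kept.groupby("group"):
        group_rows.append({
            "group": g,
            "n": len(sub),
            "n_within": int((sub["status"] == "within").sum()),
            "depth_min": float(sub["depth"].min()),
            "depth_median": float(sub["depth"].median()),
            "depth_max": float(sub["depth"].max()),
        })
    group_table = pd.DataFrame(group_rows)
    return status_table, group_table
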