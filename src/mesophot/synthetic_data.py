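"""Seeded synthetic fixtures: a toy basin with the basin-scale gradients.

The generator emulates the documented large-scale structure of the real
inputs — a water-clarity (Kd490) field decreasing along a NNW -> SSE axis,
surface PAR increasing toward the SE, a shelf-to-basin bathymetric ramp
below a northern coastline, a satellite gap hugging the coast, rectangular
reporting sub-regions, and occurrence records drawn from cells of known
above/within/below/excluded status — so that every stage of the pipeline
is testable without touching the external archives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .grid import EARTH_RADIUS_KM, GeoGrid, GridStack, GridTransform
from .light_model import OpticalParams, light_fields
from .literature_validation import GROUPS
from .zone_delineation import SubRegion, cell_areas, delineate


@dataclass(frozen=True)
class BasinSpec:
    """Parameters of the synthetic basin.

    Defaults give a 10 x 6 degree basin at 0.02 degree resolution
    (300 x 500 cells): Kd490 spanning 0.05-0.25 m^-1 and decreasing from
    the NNW corner, surface PAR spanning 30-42 mol photons m^-2 day^-1 and
    increasing toward the SE, a northern land strip, a bathymetric ramp of
    2.5 m per km down to a 3000 m floor, and a ~5 km satellite gap along
    the coast (ocean-colour products lose the shoreline cells).  The seed
    fixes all randomness.
    """

    lon_min: float = 0.0
    lon_max: float = 10.0
    lat_min: float = 34.0
    lat_max: float = 40.0
    resolution: float = 0.02
    kd490_range: tuple[float, float] = (0.05, 0.25)
    par0_range: tuple[float, float] = (30.0, 42.0)
    ramp_m_per_km: float = 2.5
    basin_floor_m: float = 3000.0
    land_fraction: float = 0.08
    satellite_gap_km: float = 5.0
    noise_sd_kd: float = 0.005
    noise_sd_par: float = 0.3
    noise_smoothing_cells: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValueError("degenerate extent")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for lo, hi in (self.kd490_range, self.par0_range):
            if not (0 < lo < hi):
                raise ValueError("ranges must be positive and ordered")

    @property
    def shape(self) -> tuple[int, int]:
        nrows = int(round((self.lat_max - self.lat_min) / self.resolution))
        ncols = int(round((self.lon_max - self.lon_min) / self.resolution))
        return nrows, ncols

    @property
    def transform(self) -> GridTransform:
        return GridTransform(lon0=self.lon_min, lat0=self.lat_max,
                             dlon=self.resolution, dlat=self.resolution)


def _smooth_noise(rng: np.random.Generator, shape, sd: float, sigma: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    s = raw.std()
    return raw * (sd / s) if s > 0 else raw


def make_basin(spec: BasinSpec = BasinSpec()) -> tuple[GeoGrid, GeoGrid, GeoGrid, np.ndarray]:
    """Generate (kd490, par0, depth, land_mask) on the spec's grid.

    Fields are linear gradients along the NNW->SSE diagonal plus seeded,
    Gaussian-smoothed noise clipped to the stated ranges.  Land cells are
    nodata in every marine grid; Kd490 and PAR are additionally nodata in
    the coastal satellite-gap strip.
    """
    nrows, ncols = spec.shape
    t = spec.transform
    rng = np.random.default_rng(spec.seed)

    x = (np.arange(ncols) + 0.5) / ncols          # 0 at W -> 1 at E
    y = 1.0 - (np.arange(nrows) + 0.5) / nrows    # 1 at N -> 0 at S
    xg, yg = np.meshgrid(x, y)
    sse = (xg + (1.0 - yg)) / 2.0                 # 0 at NNW corner, 1 at SSE corner

    k_lo, k_hi = spec.kd490_range
    kd = k_hi - (k_hi - k_lo) * sse
    kd = np.clip(kd + _smooth_noise(rng, kd.shape, spec.noise_sd_kd,
                                    spec.noise_smoothing_cells), k_lo, k_hi)
    p_lo, p_hi = spec.par0_range
    par = p_lo + (p_hi - p_lo) * sse
    par = np.clip(par + _smooth_noise(rng, par.shape, spec.noise_sd_par,
                                      spec.noise_smoothing_cells), p_lo, p_hi)

    land_rows = int(round(spec.land_fraction * nrows))
    land = np.zeros((nrows, ncols), dtype=bool)
    land[:land_rows] = True

    cell_h_km = math.radians(spec.resolution) * EARTH_RADIUS_KM
    dist_km = (np.arange(nrows) - land_rows + 0.5) * cell_h_km
    depth_col = np.clip(dist_km * spec.ramp_m_per_km, 0.0, spec.basin_floor_m)
    depth = np.broadcast_to(depth_col[:, None], (nrows, ncols)).copy()
    depth[land] = np.nan

    sat_gap = np.zeros_like(land)
    gap_cells = int(round(spec.satellite_gap_km / cell_h_km))
    if gap_cells > 0:
        sat_gap[land_rows:land_rows + gap_cells] = True
    kd[land | sat_gap] = np.nan
    par[land | sat_gap] = np.nan

    kd_g = GeoGrid(kd, t, role="kd490")
    par_g = GeoGrid(par, t, role="par0")
    depth_g = GeoGrid(depth, t, role="depth")
    return kd_g, par_g, depth_g, land


def make_ramp_fixture(
    kd490: float = 0.1,
    par0: float = 40.0,
    slope_m_per_km: float = 2.5,
    spec: BasinSpec | None = None,
) -> tuple[GeoGrid, GeoGrid, GeoGrid]:
    """Constant-optics / linear-ramp variant with a closed-form zone strip.

    Constant Kd490 and surface PAR over a bathymetry increasing linearly
    southward from the northern edge, depth(y) = slope * y.  The mesophotic
    strip is then exactly y in [30/s, z*/s] with z* the e_min isolume depth,
    giving an analytic oracle for delineation, areas and borders.
    """
    spec = spec or BasinSpec(land_fraction=0.0, satellite_gap_km=0.0, noise_sd_kd=0.0,
                             noise_sd_par=0.0)
    nrows, ncols = spec.shape
    t = spec.transform
    cell_h_km = math.radians(spec.resolution) * EARTH_RADIUS_KM
    dist_km = (np.arange(nrows) + 0.5) * cell_h_km
    depth = np.broadcast_to((dist_km * slope_m_per_km)[:, None], (nrows, ncols)).copy()
    kd = np.full((nrows, ncols), kd490)
    par = np.full((nrows, ncols), par0)
    return GeoGrid(kd, t, role="kd490"), GeoGrid(par, t, role="par0"), \
        GeoGrid(depth, t, role="depth")


def make_daily_stack(
    base: GeoGrid,
    n_days: int,
    noise_sd: float = 0.01,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> GridStack:
    """``n_days`` copies of ``base`` with iid noise and random missing cells."""
    if not (0 <= missing_fraction < 1):
        raise ValueError("missing fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    grids = []
    for _ in range(n_days):
        v = base.values + (rng.normal(0.0, noise_sd, base.shape) if noise_sd > 0 else 0.0)
        if missing_fraction > 0:
            v = np.where(rng.random(base.shape) < missing_fraction, np.nan, v)
        grids.append(base.like(v))
    dates = pd.date_range("2002-01-01", periods=n_days, freq="D")
    return GridStack(grids=grids, timestamps=list(dates))


def make_subregions(template: GeoGrid, n: int = 4) -> list[SubRegion]:
    """``n`` equal-width longitudinal rectangles tiling the grid extent,
    named R1..Rn, with reference areas from the spherical cell areas."""
    if n < 1:
        raise ValueError("need at least one sub-region")
    w, s, e, nb = template.bounds
    edges = np.linspace(w, e, n + 1)
    areas = cell_areas(template).values
    lons = template.lon_centers()
    out = []
    for i in range(n):
        poly = box(edges[i], s, edges[i + 1], nb)
        in_cols = (lons >= edges[i]) & (lons < edges[i + 1])
        ref = float(areas[:, in_cols].sum())
        out.append(SubRegion(name=f"R{i + 1}", polygon=poly, reference_area_km2=ref))
    return out


def make_records(
    kd490: GeoGrid,
    par0: GeoGrid,
    depth: GeoGrid,
    land: np.ndarray,
    counts: dict[str, int],
    seed: int = 0,
    params: OpticalParams = OpticalParams(),
    upper_depth: float = 30.0,
    max_depth: float = 500.0,
) -> pd.DataFrame:
    """Occurrence records drawn from cells of known status.

    ``counts`` maps target statuses (``above``, ``within``, ``below``,
    ``land``, ``out_of_extent``, ``deep``) to record counts.  Records are
    placed at cell centers sampled without replacement within each stratum,
    with assemblage groups assigned cyclically; the returned frame carries
    a ``truth`` column with the requested status.
    """
    rng = np.random.default_rng(seed)
    _, ez, _ = light_fields(kd490, par0, depth, params)
    zone = delineate(depth, ez, upper_depth=upper_depth, e_min=params.e_min)

    sat = kd490.valid & par0.valid
    marine = ~land
    strata = {
        "land": land,
        "out_of_extent": marine & ~sat,
        "deep": marine & sat & (depth.values > max_depth),
        "above": marine & sat & depth.valid & (depth.values < upper_depth)
                 & (depth.values > 0),
        "within": zone.true_mask & (depth.values <= max_depth),
        "below": marine & sat & depth.valid & (depth.values >= upper_depth)
                 & (depth.values <= max_depth) & (ez.values < params.e_min),
    }
    lons = kd490.lon_centers()
    lats = kd490.lat_centers()
    rows = []
    rec_id = 0
    for status in sorted(counts):
        n = counts[status]
        if status not in strata:
            raise ValueError(f"unknown stratum {status!r}")
        cells = np.flatnonzero(strata[status].ravel())
        if cells.size < n:
            raise ValueError(
                f"stratum {status!r} has only {cells.size} cells, {n} requested"
            )
        chosen = rng.choice(cells, size=n, replace=False)
        for c in np.sort(chosen):
            i, j = divmod(int(c), kd490.shape[1])
            rows.append({
                "id": f"REC{rec_id:05d}",
                "lon": float(lons[j]),
                "lat": float(lats[i]),
                "group": GROUPS[rec_id % len(GROUPS)],
                "source": "synthetic",
                "truth": status,
            })
            rec_id += 1
    return pd.DataFrame(rows)
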