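"""Zone borders: extraction, 20-km sampling, value attachment and the
sub-region comparison statistics.

The zone has two borders. The *upper* border is the landward edge where
the 30 m depth bound excludes the neighbouring seabed; the *lower* border
is the seaward edge where the minimum-irradiance isolume excludes it.
Points are laid every ``spacing`` km along each border polyline (geodesic
arc length on the R = 6371.0088 km sphere), irradiance / percent PAR /
depth are read off the nearest grid cell, and group differences among
sub-regions are tested with Kruskal-Wallis followed by Dunn's post hoc
comparisons with Bonferroni adjustment (the border variables are not
normal or homoscedastic, which :func:`assumption_screen` reports).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps

from .grid import EARTH_RADIUS_KM, GeoGrid, require_aligned
from .zone_delineation import MesophoticZone, SubRegion

logger = logging.getLogger(__name__)

Polyline = list[tuple[float, float]]  # [(lon, lat), ...]


# ---------------------------------------------------------------------------
# border geometry

def extract_borders(zone: MesophoticZone) -> tuple[list[Polyline], list[Polyline]]:
    """Trace the upper (depth-bound) and lower (isolume) border polylines.

    A mask-true cell contributes the edge it shares with a valid false
    neighbour; the edge is *upper* if the neighbour fails the depth test
    (too shallow) — including corner cells failing both tests, since the
    30 m bound is the definitionally fixed one — and *lower* if it fails
    only the light test.  Edges against nodata cells or the raster edge
    belong to neither border.
    """
    t = zone.mask.transform
    true = zone.true_mask
    depth = zone.depth.values
    ez = zone.ez.values
    lon_e = t.lon_edges(true.shape[1])
    lat_e = t.lat_edges(true.shape[0])

    upper_segs: list[tuple[tuple[float, float], tuple[float, float]]] = []
    lower_segs: list[tuple[tuple[float, float], tuple[float, float]]] = []

    def classify(i: int, j: int) -> str | None:
        """Which constraint excludes valid false cell (i, j)."""
        d, e = depth[i, j], ez[i, j]
        if not (np.isfinite(d) and np.isfinite(e)):
            return None
        if d < zone.upper_depth:
            return "upper"
        if e < zone.e_min:
            return "lower"
        return None  # cannot happen for a false cell of a consistent mask

    nrows, ncols = true.shape
    ti, tj = np.nonzero(true)
    for i, j in zip(ti.tolist(), tj.tolist()):
        # (di, dj, segment endpoints on the shared edge)
        for di, dj, p0, p1 in (
            (0, -1, (lon_e[j], lat_e[i + 1]), (lon_e[j], lat_e[i])),          # west
            (0, 1, (lon_e[j + 1], lat_e[i + 1]), (lon_e[j + 1], lat_e[i])),   # east
            (-1, 0, (lon_e[j], lat_e[i]), (lon_e[j + 1], lat_e[i])),          # north
            (1, 0, (lon_e[j], lat_e[i + 1]), (lon_e[j + 1], lat_e[i + 1])),   # south
        ):
            ni, nj = i + di, j + dj
            if not (0 <= ni < nrows and 0 <= nj < ncols):
                continue  # raster edge: excluded from both borders
            if true[ni, nj] or not np.isfinite(zone.mask.values[ni, nj]):
                continue
            side = classify(ni, nj)
            if side == "upper":
                upper_segs.append((p0, p1))
            elif side == "lower":
                lower_segs.append((p0, p1))

    return _chain_segments(upper_segs), _chain_segments(lower_segs)


def _key(pt: tuple[float, float]) -> tuple[float, float]:
    return (round(pt[0], 9), round(pt[1], 9))


def _chain_segments(segments) -> list[Polyline]:
    """Join shared-endpoint segments into polylines, deterministically.

    Open chains are walked first (starting from odd-degree nodes in sorted
    order), then any remaining closed loops.
    """
    if not segments:
        return []
    adj: dict[tuple[float, float], list[int]] = {}
    for idx, (p0, p1) in enumerate(segments):
        adj.setdefault(_key(p0), []).append(idx)
        adj.setdefault(_key(p1), []).append(idx)
    used = [False] * len(segments)
    lines: list[Polyline] = []

    def walk(start: tuple[float, float]) -> Polyline:
        line = [start]
        node = start
        while True:
            nxt = None
            for idx in sorted(adj[node]):
                if not used[idx]:
                    nxt = idx
                    break
            if nxt is None:
                return line
            used[nxt] = True
            p0, p1 = _key(segments[nxt][0]), _key(segments[nxt][1])
            node = p1 if p0 == node else p0
            line.append(node)

    odd = sorted(n for n, idxs in adj.items() if len(idxs) % 2 == 1)
    for node in odd:
        if any(not used[i] for i in adj[node]):
            lines.append(walk(node))
    for node in sorted(adj):  # leftover loops
        if any(not used[i] for i in adj[node]):
            lines.append(walk(node))
    return lines


def geodesic_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance on the authalic sphere (haversine)."""
    lon1, lat1, lon2, lat2 = map(np.radians, map(np.asarray, (lon1, lat1, lon2, lat2)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def polyline_length_km(line: Polyline) -> float:
    if len(line) < 2:
        return 0.0
    pts = np.asarray(line)
    return float(geodesic_km(pts[:-1, 0], pts[:-1, 1], pts[1:, 0], pts[1:, 1]).sum())


def sample_along(lines: list[Polyline], spacing_km: float = 20.0) -> list[tuple[float, float]]:
    """Points at arc length 0, s, 2s, ... from the start of each polyline.

    A polyline shorter than the spacing contributes its start point only;
    per line the count is floor(length / spacing) + 1.
    """
    if spacing_km <= 0:
        raise ValueError("spacing must be positive")
    points: list[tuple[float, float]] = []
    for line in lines:
        if not line:
            continue
        pts = np.asarray(line, dtype=float)
        if len(pts) == 1:
            points.append((float(pts[0, 0]), float(pts[0, 1])))
            continue
        seg = geodesic_km(pts[:-1, 0], pts[:-1, 1], pts[1:, 0], pts[1:, 1])
        cum = np.concatenate(([0.0], np.cumsum(seg)))
        n = int(math.floor(cum[-1] / spacing_km)) + 1
        targets = np.arange(n) * spacing_km
        for d in targets:
            k = int(np.searchsorted(cum, d, side="right") - 1)
            k = min(k, len(seg) - 1)
            frac = 0.0 if seg[k] == 0 else (d - cum[k]) / seg[k]
            lon = pts[k, 0] + frac * (pts[k + 1, 0] - pts[k, 0])
            lat = pts[k, 1] + frac * (pts[k + 1, 1] - pts[k, 1])
            points.append((float(lon), float(lat)))
    return points


def attach_values(
    points: list[tuple[float, float]],
    ez: GeoGrid,
    percent: GeoGrid,
    depth: GeoGrid,
    subregions: list[SubRegion] | None = None,
    border: str = "upper",
) -> pd.DataFrame:
    """Nearest-cell irradiance / percent PAR / depth at each border point.

    Points whose nearest cell is nodata are dropped (count logged);
    sub-region membership is by point-in-polygon, first match wins.
    """
    require_aligned(ez, percent, depth)
    if not points:
        return pd.DataFrame(columns=["lon", "lat", "border", "irradiance",
                                     "percent_par", "depth", "subregion"])
    pts = np.asarray(points, dtype=float)
    vals = {
        "irradiance": ez.sample_nearest(pts[:, 0], pts[:, 1]),
        "percent_par": percent.sample_nearest(pts[:, 0], pts[:, 1]),
        "depth": depth.sample_nearest(pts[:, 0], pts[:, 1]),
    }
    df = pd.DataFrame({"lon": pts[:, 0], "lat": pts[:, 1], "border": border, **vals})
    keep = df[["irradiance", "percent_par", "depth"]].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("attach_values: %d point(s) on nodata dropped", n_dropped)
    df = df[keep].reset_index(drop=True)
    region = pd.Series([None] * len(df), dtype=object)
    if subregions:
        unassigned = np.ones(len(df), dtype=bool)
        for sr in subregions:
            if not unassigned.any():
                break
            hit = shapely.contains_xy(sr.polygon, df["lon"].to_numpy(), df["lat"].to_numpy())
            take = unassigned & hit
            region[take] = sr.name
            unassigned &= ~take
    df["subregion"] = region
    return df


def summarize(
    samples: pd.DataFrame,
    by: str = "subregion",
    variable: str = "irradiance",
) -> pd.DataFrame:
    """Mean +- standard error (sd/sqrt(n)) per group, or pooled (``by="basin"``)."""
    if samples.empty:
        raise ValueError("no samples to summarize")
    if variable not in samples.columns:
        raise ValueError(f"unknown variable {variable!r}")

    def row(name, v):
        v = np.asarray(v, dtype=float)
        se = 0.0 if v.size < 2 else float(np.std(v, ddof=1) / math.sqrt(v.size))
        return {"group": name, "n": int(v.size), "mean": float(np.mean(v)), "se": se}

    if by == "basin":
        return pd.DataFrame([row("Basin", samples[variable])])
    rows = [row(g, sub[variable]) for g, sub in samples.groupby(by, dropna=True) if len(sub)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank statistics

@dataclass
class RankTestResult:
    """Kruskal-Wallis H with chi-square p, plus Dunn-Bonferroni pairwise p."""

    H: float
    df: int
    p: float
    pairwise: pd.DataFrame | None = None


def kruskal_wallis(groups: list[np.ndarray]) -> RankTestResult:
    """Kruskal-Wallis rank test across groups (mid-rank ties, standard
    tie-correction divisor, chi-square upper-tail p with df = k - 1).

    Degenerate all-identical input yields H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    _check_groups(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return RankTestResult(H=0.0, df=len(groups) - 1, p=1.0)
    H, p = sps.kruskal(*groups)
    return RankTestResult(H=float(H), df=len(groups) - 1, p=float(p))


def dunn_posthoc(groups: list[np.ndarray], names: list[str] | None = None) -> pd.DataFrame:
    """Dunn's multiple-comparison z tests on mean ranks, Bonferroni adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)) with
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p multiplied
    by the k(k-1)/2 comparisons and capped at 1.  Returns a symmetric matrix
    with unit diagonal.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    _check_groups(groups)
    k = len(groups)
    names = names or [f"g{i + 1}" for i in range(k)]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    m = k * (k - 1) / 2
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            denom = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if denom == 0:
                p = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / denom
                p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
            P[i, j] = P[j, i] = p
    return pd.DataFrame(P, index=names, columns=names)


def assumption_screen(groups: list[np.ndarray]) -> tuple[list[float], float]:
    """Shapiro-Wilk normality p per group and median-centered Levene
    (Brown-Forsythe) homoscedasticity p across groups.

    Advisory only — it never gates the rank tests.  Groups with n < 3 get
    NaN normality p; all-constant input returns homoscedasticity p = 1 by
    convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    normality = []
    for g in groups:
        if g.size < 3 or np.all(g == g[0]):
            normality.append(float("nan") if g.size < 3 else 1.0)
        else:
            normality.append(float(sps.shapiro(g).pvalue))
    if all(np.all(g == g[0]) for g in groups):
        homo = 1.0
    else:
        homo = float(sps.levene(*groups, center="median").pvalue)
    return normality, homo


def _check_groups(groups) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 1 for g in groups):
        raise ValueError("every group needs at least one value")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least three values in total")
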