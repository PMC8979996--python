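"""Border extraction/sampling geometry and the rank-test statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mesophot import (EARTH_RADIUS_KM, GeoGrid, GridTransform, assumption_screen,
                      attach_values, dunn_posthoc, extract_borders, kruskal_wallis,
                      sample_along, summarize)
from mesophot.border_stats import geodesic_km, polyline_length_km
from mesophot.zone_delineation import MesophoticZone


# ---------------------------------------------------------------------------
# geometry

class TestExtractBorders:
    def test_strip_fixture_yields_one_line_per_border(self, ramp):
        upper, lower = extract_borders(ramp["zone"])
        assert len(upper) == 1 and len(lower) == 1
        # straight east-west lines at the expected edge latitudes
        up_lats = {round(lat, 9) for _, lat in upper[0]}
        lo_lats = {round(lat, 9) for _, lat in lower[0]}
        assert len(up_lats) == 1 and len(lo_lats) == 1
        assert max(up_lats) > max(lo_lats)  # upper border is landward (north)

    def test_upper_border_sits_at_the_depth_bound(self, ramp):
        upper, _ = extract_borders(ramp["zone"])
        t = ramp["zone"].mask.transform
        lat = upper[0][0][1]
        depths = ramp["depth"].values[:, 0]
        first_zone_row = int(np.flatnonzero(ramp["zone"].true_mask[:, 0])[0])
        assert lat == pytest.approx(t.lat0 - first_zone_row * t.dlat)
        # that row is the first at or below 30 m
        assert depths[first_zone_row] >= 30.0 > depths[first_zone_row - 1]

    def test_island_bounded_by_shallow_cells_is_all_upper(self):
        t = GridTransform(0.0, 5.0, 1.0, 1.0)
        depth = np.full((5, 5), 20.0)
        depth[2, 2] = 60.0
        ez = np.full((5, 5), 1.0)
        mask = np.zeros((5, 5))
        mask[2, 2] = 1.0
        zone = MesophoticZone(GeoGrid(mask, t), GeoGrid(depth, t, role="depth"),
                              GeoGrid(ez, t, role="ez"))
        upper, lower = extract_borders(zone)
        assert lower == []
        assert sum(polyline_length_km(l) for l in upper) > 0

    def test_raster_edge_segments_belong_to_neither_border(self, ramp):
        upper, lower = extract_borders(ramp["zone"])
        w, _, e, _ = ramp["zone"].mask.bounds
        for line in upper + lower:
            lons = [lon for lon, _ in line]
            # the strip runs wall-to-wall, so only horizontal edges qualify;
            # no vertical segment may run along the raster sides
            assert all(w <= lon <= e for lon in lons)
        # both borders are purely horizontal single-latitude lines
        assert len({lat for _, lat in upper[0]}) == 1

    def test_corner_cell_failing_both_tests_goes_to_upper(self):
        # neighbour both too shallow and too dark -> attributed to the fixed
        # depth bound
        t = GridTransform(0.0, 1.0, 1.0, 1.0)
        depth = np.array([[20.0, 60.0]])
        ez = np.array([[1e-6, 1.0]])
        mask = np.array([[0.0, 1.0]])
        zone = MesophoticZone(GeoGrid(mask, t), GeoGrid(depth, t, role="depth"),
                              GeoGrid(ez, t, role="ez"))
        upper, lower = extract_borders(zone)
        assert len(upper) == 1 and lower == []

    def test_empty_zone_gives_empty_borders(self):
        t = GridTransform(0.0, 2.0, 1.0, 1.0)
        zone = MesophoticZone(GeoGrid(np.zeros((2, 2)), t),
                              GeoGrid(np.full((2, 2), 10.0), t, role="depth"),
                              GeoGrid(np.ones((2, 2)), t, role="ez"))
        assert extract_borders(zone) == ([], [])


class TestSampleAlong:
    def _merid_line(self, length_km):
        # a meridian arc of the requested geodesic length
        dlat = length_km / (math.radians(1.0) * EARTH_RADIUS_KM)
        return [(0.0, 0.0), (0.0, dlat)]

    @pytest.mark.parametrize("length_km, expected", [(100.0, 6), (19.9, 1),
                                                     (40.0, 3), (0.5, 1)])
    def test_point_count_is_floor_length_over_spacing_plus_one(self, length_km,
                                                               expected):
        pts = sample_along([self._merid_line(length_km)], 20.0)
        assert len(pts) == expected

    def test_points_are_evenly_spaced_in_arc_length(self):
        pts = sample_along([self._merid_line(100.0)], 20.0)
        d = [geodesic_km(pts[i][0], pts[i][1], pts[i + 1][0], pts[i + 1][1])
             for i in range(len(pts) - 1)]
        assert np.allclose(d, 20.0, rtol=1e-6)

    def test_strip_border_count_matches_length_formula(self, ramp):
        upper, _ = extract_borders(ramp["zone"])
        pts = sample_along(upper, 20.0)
        total = sum(math.floor(polyline_length_km(l) / 20.0) + 1 for l in upper)
        assert len(pts) == total

    def test_nonpositive_spacing_is_rejected(self):
        with pytest.raises(ValueError):
            sample_along([self._merid_line(10)], 0.0)


class TestAttachValues:
    def test_point_at_cell_center_reads_that_cell(self, ramp):
        g = ramp["ez"]
        lon = g.lon_centers()[7]
        lat = g.lat_centers()[9]
        df = attach_values([(lon, lat)], ramp["ez"], ramp["percent"], ramp["depth"])
        assert df.loc[0, "irradiance"] == g.values[9, 7]
        assert df.loc[0, "depth"] == ramp["depth"].values[9, 7]

    def test_point_on_nodata_is_dropped(self, ramp):
        ez = ramp["ez"].like(ramp["ez"].values.copy())
        ez.values[0, 0] = np.nan
        lon = ez.lon_centers()[0]
        lat = ez.lat_centers()[0]
        df = attach_values([(lon, lat)], ez, ramp["percent"], ramp["depth"])
        assert len(df) == 0

    def test_upper_samples_sit_within_half_a_cell_of_the_depth_bound(self, ramp):
        upper, _ = extract_borders(ramp["zone"])
        pts = sample_along(upper, 20.0)
        df = attach_values(pts, ramp["ez"], ramp["percent"], ramp["depth"],
                           border="upper")
        t = ramp["depth"].transform
        dz_cell = ramp["slope"] * math.radians(t.dlat) * EARTH_RADIUS_KM
        assert np.all(np.abs(df["depth"] - 30.0) <= dz_cell)

    def test_lower_samples_irradiance_within_discretization_band(self, ramp):
        _, lower = extract_borders(ramp["zone"])
        pts = sample_along(lower, 20.0)
        df = attach_values(pts, ramp["ez"], ramp["percent"], ramp["depth"],
                           border="lower")
        t = ramp["depth"].transform
        dz = ramp["slope"] * math.radians(t.dlat) * EARTH_RADIUS_KM
        kdpar = ramp["kdpar"].values[0, 0]
        e_min = ramp["zone"].e_min
        lo, hi = e_min * math.exp(-kdpar * dz), e_min * math.exp(kdpar * dz)
        assert np.all((df["irradiance"] >= lo) & (df["irradiance"] <= hi))


class TestSummarize:
    def test_mean_and_standard_error(self):
        df = pd.DataFrame({"irradiance": [1.0, 2.0, 3.0], "subregion": "A",
                           "border": "upper"})
        out = summarize(df, by="subregion", variable="irradiance")
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "se"] == pytest.approx(1 / math.sqrt(3))

    def test_single_sample_has_zero_se(self):
        df = pd.DataFrame({"depth": [175.0], "subregion": "A", "border": "lower"})
        out = summarize(df, by="subregion", variable="depth")
        assert out.loc[0, "se"] == 0.0

    def test_pooled_basin_mean_lies_between_group_means(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "percent_par": np.concatenate([rng.uniform(5, 7, 30),
                                           rng.uniform(10, 14, 50)]),
            "subregion": ["A"] * 30 + ["B"] * 50,
        })
        groups = summarize(df, by="subregion", variable="percent_par")
        basin = summarize(df, by="basin", variable="percent_par")
        assert groups["mean"].min() <= basin.loc[0, "mean"] <= groups["mean"].max()


# ---------------------------------------------------------------------------
# rank statistics

def _kw_oracle(groups):
    """Rank-sum formula with mid-rank ties and the standard tie correction."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    splits = np.cumsum([g.size for g in groups])[:-1]
    h = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / r.size for r in np.split(ranks, splits)) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    denom = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    return 0.0 if denom == 0 else h / denom


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        res = kruskal_wallis([np.arange(1, 4), np.arange(4, 7), np.arange(7, 10)])
        # rank sums 6, 15, 24 -> 12/90 * (12 + 75 + 192) - 30 = 7.2
        assert res.H == pytest.approx(7.2, abs=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(sps.chi2.sf(7.2, 2), rel=1e-12)

    def test_identical_groups_give_zero_statistic(self):
        res = kruskal_wallis([np.ones(4), np.ones(4)])
        assert res.H == 0.0 and res.p == 1.0

    def test_matches_rank_formula_oracle_exhaustively_small_n(self):
        # every assignment of values {1, 2, 3} to three groups of two (N = 6)
        for vals in itertools.product([1.0, 2.0, 3.0], repeat=6):
            groups = [np.array(vals[:2]), np.array(vals[2:4]), np.array(vals[4:])]
            assert kruskal_wallis(groups).H == pytest.approx(_kw_oracle(groups),
                                                             abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=8, unique=True))
    def test_invariant_under_monotone_transform(self, values):
        values = np.asarray(values, dtype=float)
        k = len(values) // 2
        groups = [values[:k], values[k:]]
        trans = [np.exp(g / 20.0) for g in groups]
        assert kruskal_wallis(groups).H == pytest.approx(
            kruskal_wallis(trans).H, rel=1e-9)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.arange(5.0)])


class TestDunnPosthoc:
    def test_identical_groups_give_all_ones(self):
        out = dunn_posthoc([np.ones(3), np.ones(3), np.ones(3)])
        assert (out.values == 1.0).all()

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        out = dunn_posthoc([rng.normal(size=8), rng.normal(1, 1, 9),
                            rng.normal(2, 1, 7)])
        assert np.allclose(out.values, out.values.T)
        assert np.allclose(np.diag(out.values), 1.0)

    def test_most_separated_pair_has_smallest_adjusted_p(self):
        out = dunn_posthoc([np.arange(1.0, 4), np.arange(4.0, 7), np.arange(7.0, 10)],
                           names=["a", "b", "c"])
        assert out.loc["a", "c"] == out.values[~np.eye(3, dtype=bool)].min()

    def test_bonferroni_adjustment_never_lowers_p(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=10), rng.normal(0.5, 1, 10), rng.normal(1, 1, 10)]
        adjusted = dunn_posthoc(groups)
        # recompute one raw z by hand and check the 3x scaling (capped at 1)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        r = np.split(ranks, [10, 20])
        n = pooled.size
        z = (r[0].mean() - r[1].mean()) / math.sqrt(
            (n * (n + 1) / 12.0) * (1 / 10 + 1 / 10))
        raw = 2 * sps.norm.sf(abs(z))
        assert adjusted.iloc[0, 1] == pytest.approx(min(1.0, raw * 3), rel=1e-9)


class TestAssumptionScreen:
    def test_normal_draws_give_uniform_normality_p(self):
        # Shapiro p under the null is U(0,1): KS over 200 seeded replicates
        ps = []
        for seed in range(200):
            g = np.random.default_rng(seed).normal(size=50)
            ps.append(assumption_screen([g, g + 1.0])[0][0])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_heavy_skew_is_detected(self):
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed).exponential(size=200)
            if assumption_screen([g, g])[0][0] < 0.01:
                hits += 1
        assert hits >= 95

    def test_identical_groups_homoscedastic_by_convention(self):
        normality, homo = assumption_screen([np.full(5, 2.0), np.full(6, 2.0)])
        assert homo == 1.0
        assert normality == [1.0, 1.0]

    def test_undersized_group_gets_nan_normality(self):
        normality, _ = assumption_screen([np.array([1.0, 2.0]),
                                          np.array([1.0, 2.0, 3.0, 4.0])])
        assert math.isnan(normality[0])
        assert not math.isnan(normality[1])
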