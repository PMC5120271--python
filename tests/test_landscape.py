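"""Elliptical buffers, zonal vegetation cover, road gaps, distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString

from feedernet.errors import GeometryError, ValidationError
from feedernet.landscape import (
    build_pair_features,
    count_road_gaps,
    ellipse_for_pair,
    features_summary,
    pair_distance,
    read_roads,
    ringing_distance,
    vegetation_cover,
    write_roads,
)
from feedernet.raster import Raster

finite = st.floats(-5000, 5000, allow_nan=False)


class TestEllipse:
    def test_horizontal_pair_axes(self):
        e = ellipse_for_pair((0.0, 0.0), (100.0, 0.0))
        assert e.center == (50.0, 0.0)
        assert e.semi_major == 75.0
        assert e.semi_minor == 25.0

    @given(finite, finite, finite, finite)
    @settings(max_examples=100, deadline=None)
    def test_axis_ratio_exactly_three(self, ax, ay, bx, by):
        if (ax, ay) == (bx, by):
            return
        e = ellipse_for_pair((ax, ay), (bx, by))
        assert abs(e.semi_major / e.semi_minor - 3.0) < 1e-12
        d = np.hypot(bx - ax, by - ay)
        # buffer margin beyond each feeder is a quarter of the distance
        assert abs((2 * e.semi_major - d) / (2 * d) - 0.25) < 1e-12
        # both feeders lie inside
        assert e.contains(np.array([ax, bx]), np.array([ay, by])).all()

    def test_rotation_leaves_area_invariant(self, rng):
        a = np.array([12.0, -7.0])
        b = np.array([80.0, 33.0])
        d = np.hypot(*(b - a))
        expected = np.pi * 0.75 * d * 0.25 * d
        for theta in rng.uniform(0, 2 * np.pi, size=5):
            R = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            e = ellipse_for_pair(R @ a, R @ b)
            assert e.area == pytest.approx(expected, rel=1e-12)

    def test_coincident_stations_error(self):
        with pytest.raises(GeometryError):
            ellipse_for_pair((1.0, 1.0), (1.0, 1.0))


def _flat_raster(value, n=60, cellsize=2.0):
    return Raster(np.full((n, n), float(value)), x_ll=0.0, y_ll=0.0,
                  cellsize=cellsize)


class TestVegetationCover:
    def test_uniformly_vegetated_is_100(self):
        e = ellipse_for_pair((30.0, 60.0), (90.0, 60.0))
        h = _flat_raster(3.0)
        idx = _flat_raster(0.8)
        assert vegetation_cover(e, h, idx) == 100.0

    def test_uniformly_bare_is_0(self):
        e = ellipse_for_pair((30.0, 60.0), (90.0, 60.0))
        assert vegetation_cover(e, _flat_raster(0.0), _flat_raster(-0.1)) == 0.0

    def test_height_and_index_are_conjoined(self):
        e = ellipse_for_pair((30.0, 60.0), (90.0, 60.0))
        # tall but index below threshold -> not vegetation
        assert vegetation_cover(e, _flat_raster(3.0), _flat_raster(0.0)) == 0.0
        # index test can be disabled by omitting the raster
        assert vegetation_cover(e, _flat_raster(3.0), None) == 100.0

    def test_matches_bruteforce_pixel_loop(self, rng):
        """Seeded random raster: cover equals 100k/n computed by explicit
        enumeration of pixel centers."""
        n = 70
        h = Raster(
            rng.uniform(0, 2.0, size=(n, n)), x_ll=0.0, y_ll=0.0, cellsize=2.0
        )
        idx = Raster(
            rng.uniform(-0.5, 0.9, size=(n, n)), x_ll=0.0, y_ll=0.0, cellsize=2.0
        )
        e = ellipse_for_pair((25.0, 40.0), (110.0, 95.0))
        got = vegetation_cover(e, h, idx)
        k = m = 0
        for row in range(n):
            for col in range(n):
                x = 0.0 + (col + 0.5) * 2.0
                y = 0.0 + (n - row - 0.5) * 2.0
                if e.contains(x, y):
                    m += 1
                    if h.data[row, col] > 0.7 and idx.data[row, col] > 0.2:
                        k += 1
        assert m > 0
        assert got == pytest.approx(100.0 * k / m, abs=1e-9)

    def test_cover_monotone_when_vegetating_pixels(self, rng):
        n = 60
        data = rng.uniform(0, 0.5, size=(n, n))
        e = ellipse_for_pair((30.0, 60.0), (90.0, 60.0))
        cover = []
        h = Raster(data.copy(), 0.0, 0.0, 2.0)
        for _ in range(4):
            cover.append(vegetation_cover(e, h, None))
            bare = np.argwhere(h.data <= 0.7)
            pick = bare[rng.integers(len(bare), size=50)]
            h.data[pick[:, 0], pick[:, 1]] = 5.0
        assert all(a <= b for a, b in zip(cover, cover[1:]))

    def test_ellipse_outside_raster_errors(self):
        e = ellipse_for_pair((5000.0, 5000.0), (5100.0, 5000.0))
        with pytest.raises(GeometryError):
            vegetation_cover(e, _flat_raster(1.0), None)


class TestRoadGaps:
    def test_no_roads(self):
        e = ellipse_for_pair((0.0, 0.0), (100.0, 0.0))
        assert count_road_gaps(e, []) == (0, 0)

    def test_three_distinct_roads_pool_to_class_two(self):
        e = ellipse_for_pair((0.0, 0.0), (100.0, 0.0))
        roads = [
            LineString([(20, -50), (20, 50)]),
            LineString([(50, -50), (50, 50)]),
            LineString([(80, -50), (80, 50)]),
        ]
        assert count_road_gaps(e, roads) == (3, 2)

    def test_road_crossing_twice_counts_once(self):
        e = ellipse_for_pair((0.0, 0.0), (100.0, 0.0))
        zigzag = LineString([(20, -50), (20, 50), (80, 50), (80, -50)])
        assert count_road_gaps(e, [zigzag]) == (1, 1)

    def test_tangent_outside_does_not_count(self):
        """A road skimming past the ellipse never enters its interior;
        verified against dense point sampling."""
        e = ellipse_for_pair((0.0, 0.0), (100.0, 0.0))
        # ellipse spans y in [-25, 25]; line at y = 25.5 stays outside
        line = LineString([(-100, 25.5), (200, 25.5)])
        ts = np.linspace(0, 1, 20001)
        pts_x = -100 + ts * 300
        pts_y = np.full_like(pts_x, 25.5)
        assert not e.contains(pts_x, pts_y).any()
        assert count_road_gaps(e, [line]) == (0, 0)

    def test_geojson_round_trip(self, tmp_path):
        roads = [
            LineString([(0, 0), (10, 10)]),
            LineString([(5, -5), (5, 20)]),
        ]
        write_roads(roads, tmp_path / "roads.geojson")
        back = read_roads(tmp_path / "roads.geojson")
        assert len(back) == 2
        assert all(a.equals(b) for a, b in zip(roads, back))


class TestDistances:
    def test_three_four_five(self):
        assert pair_distance((0.0, 0.0), (3.0, 4.0)) == 5.0

    def test_ringing_distance_takes_nearest_combination(self):
        sites = pd.DataFrame(
            {
                "site_id": ["R1", "R2"],
                "network_id": ["net", "net"],
                "x": [0.0, 1000.0],
                "y": [0.0, 0.0],
            }
        )
        assert ringing_distance((10.0, 0.0), (900.0, 0.0), sites, "net") == 10.0

    def test_ringing_distance_matches_enumeration(self, rng):
        for _ in range(20):
            sites = pd.DataFrame(
                {
                    "site_id": [f"R{i}" for i in range(3)],
                    "network_id": ["net"] * 3,
                    "x": rng.uniform(0, 500, 3),
                    "y": rng.uniform(0, 500, 3),
                }
            )
            a = tuple(rng.uniform(0, 500, 2))
            b = tuple(rng.uniform(0, 500, 2))
            brute = min(
                np.hypot(p[0] - s.x, p[1] - s.y)
                for p in (a, b)
                for s in sites.itertuples()
            )
            assert ringing_distance(a, b, sites, "net") == pytest.approx(brute)

    def test_no_site_in_network_errors(self):
        sites = pd.DataFrame(
            {"site_id": ["R1"], "network_id": ["other"], "x": [0.0], "y": [0.0]}
        )
        with pytest.raises(ValidationError):
            ringing_distance((0.0, 0.0), (1.0, 1.0), sites, "net")


class TestPairFeatures:
    def test_seventeen_stations_give_136_pairs(self, full_study):
        f = full_study.features
        assert (f.groupby("network_id").size() == 136).all()

    def test_constant_cover_reported_exactly(self, rng):
        stations = pd.DataFrame(
            {
                "feeder_id": ["A", "B", "C"],
                "network_id": ["n"] * 3,
                "x": [40.0, 100.0, 70.0],
                "y": [60.0, 60.0, 100.0],
            }
        )
        sites = pd.DataFrame(
            {"site_id": ["R"], "network_id": ["n"], "x": [40.0], "y": [60.0]}
        )
        h = _flat_raster(3.0, n=100)
        idx = _flat_raster(0.9, n=100)
        feats = build_pair_features(stations, sites, h, idx, [])
        assert len(feats) == 3
        assert (feats["veg_cover_pct"] == 100.0).all()
        summary = features_summary(feats)
        assert summary["mean_veg_cover_pct"].iloc[0] == 100.0

    def test_components_recompose(self, small_study):
        """Each pair-features row equals an independent recomputation
        from the component operations."""
        study = small_study
        feats = study.features
        st_idx = study.stations.set_index("feeder_id")
        for _, row in feats.sample(10, random_state=0).iterrows():
            a = st_idx.loc[row["feeder_a"]]
            b = st_idx.loc[row["feeder_b"]]
            pa = (a["x"], a["y"])
            pb = (b["x"], b["y"])
            net = row["network_id"]
            assert row["distance_m"] == pytest.approx(pair_distance(pa, pb))
            e = ellipse_for_pair(pa, pb)
            assert row["veg_cover_pct"] == pytest.approx(
                vegetation_cover(e, study.height[net], study.index[net])
            )
            raw, cls = count_road_gaps(e, study.roads[net])
            assert (row["road_gaps_raw"], row["road_gap_class"]) == (raw, cls)
            assert row["ringing_dist_m"] == pytest.approx(
                ringing_distance(pa, pb, study.sites, net)
            )


def test_raster_ascii_round_trip(tmp_path, rng):
    r = Raster(rng.uniform(0, 10, size=(15, 22)), x_ll=3.5, y_ll=-2.0,
               cellsize=2.0)
    r.write_ascii(tmp_path / "r.asc")
    back = Raster.read_ascii(tmp_path / "r.asc")
    assert back.same_grid(r)
    np.testing.assert_allclose(back.data, r.data, rtol=1e-5)
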