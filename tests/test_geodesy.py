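"""Spherical geometry against independent closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gulltrack import geodesy

R = geodesy.EARTH_RADIUS_KM


def haversine_km(lat1, lon1, lat2, lon2):
    """Independent haversine oracle."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * R * np.arcsin(np.sqrt(a))


class TestGreatCircle:
    def test_identity_is_zero(self):
        assert geodesy.great_circle_km(37.39, 129.24, 37.39, 129.24) == 0.0

    def test_antipodal_meridian_arc(self):
        half = np.pi * R
        assert geodesy.great_circle_km(0, 0, 0, 180) == pytest.approx(half, abs=0.5)

    def test_study_sites_against_haversine(self):
        mine = geodesy.great_circle_km(68.833, 170.500, 37.390, 129.240)
        assert abs(mine - haversine_km(68.833, 170.500, 37.390, 129.240)) < 0.1

    def test_random_pairs_against_haversine(self):
        rng = np.random.default_rng(0)
        lat1, lat2 = rng.uniform(-89, 89, (2, 1000))
        lon1, lon2 = rng.uniform(-180, 180, (2, 1000))
        diff = np.abs(geodesy.great_circle_km(lat1, lon1, lat2, lon2)
                      - haversine_km(lat1, lon1, lat2, lon2))
        assert diff.max() < 0.1

    @given(st.lists(st.tuples(st.floats(-89, 89), st.floats(-180, 180)),
                    min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_triangle_inequality(self, pts):
        (a, b, c) = pts
        ab = geodesy.great_circle_km(a[0], a[1], b[0], b[1])
        bc = geodesy.great_circle_km(b[0], b[1], c[0], c[1])
        ac = geodesy.great_circle_km(a[0], a[1], c[0], c[1])
        assert ac <= ab + bc + 1e-6


class TestSphericalMean:
    def test_single_point(self):
        assert geodesy.spherical_mean([55.0], [141.0]) == pytest.approx((55.0, 141.0))

    def test_symmetry_about_meridian(self):
        lat, lon = geodesy.spherical_mean([50, 50], [10, 30])
        assert lon == pytest.approx(20.0, abs=1e-9)

    def test_antimeridian_cluster_matches_bruteforce_minimizer(self):
        lats, lons = [10.0, 12.0], [179.0, -179.0]
        la, lo = geodesy.spherical_mean(lats, lons)
        assert abs(abs(lo) - 180.0) < 1.0  # near the antimeridian, not 0
        # brute-force minimizer of summed squared great-circle distance
        cand_lat = np.arange(9.0, 13.01, 0.02)
        cand_lon = np.concatenate([np.arange(178.0, 180.0, 0.02),
                                   np.arange(-180.0, -178.0, 0.02)])
        gl, gn = np.meshgrid(cand_lat, cand_lon)
        cost = sum(geodesy.great_circle_km(gl, gn, p, q) ** 2 for p, q in zip(lats, lons))
        i = np.unravel_index(np.argmin(cost), cost.shape)
        assert la == pytest.approx(gl[i], abs=0.05)
        assert abs(geodesy.wrap_lon(lo - gn[i])) < 0.05

    def test_balanced_antipodes_raise(self):
        with pytest.raises(ValueError):
            geodesy.spherical_mean([0, 0], [0, 180])


class TestPathLength:
    def test_collinear_equatorial_degrees(self):
        assert geodesy.path_length_km([0, 0, 0], [0, 1, 2]) == pytest.approx(
            2 * np.pi * R / 180, rel=1e-6)

    def test_reversal_invariant(self):
        rng = np.random.default_rng(1)
        lat, lon = rng.uniform(-60, 60, 20), rng.uniform(-180, 180, 20)
        assert geodesy.path_length_km(lat, lon) == pytest.approx(
            geodesy.path_length_km(lat[::-1], lon[::-1]))

    def test_single_fix_is_zero(self):
        assert geodesy.path_length_km([5.0], [5.0]) == 0.0


def _cross_track_km(plat, plon, alat, alon, blat, blon):
    """Oracle: distance from point P to great-circle segment AB."""
    a = geodesy._to_unit_vectors(alat, alon)
    b = geodesy._to_unit_vectors(blat, blon)
    p = geodesy._to_unit_vectors(plat, plon)
    axis = np.cross(a, b)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return geodesy.great_circle_km(plat, plon, alat, alon)
    axis = axis / norm
    xt = abs(np.arcsin(np.clip(np.dot(p, axis), -1, 1))) * R
    # check projection falls inside the arc, else use endpoint distance
    ang_ab = np.arccos(np.clip(np.dot(a, b), -1, 1))
    proj = p - np.dot(p, axis) * axis
    proj = proj / np.linalg.norm(proj)
    inside = (np.arccos(np.clip(np.dot(proj, a), -1, 1)) <= ang_ab + 1e-12 and
              np.arccos(np.clip(np.dot(proj, b), -1, 1)) <= ang_ab + 1e-12)
    if inside:
        return xt
    return min(geodesy.great_circle_km(plat, plon, alat, alon),
               geodesy.great_circle_km(plat, plon, blat, blon))


class TestRegularize:
    @staticmethod
    def _fixes(times, lats, lons):
        return pd.DataFrame({"timestamp": pd.to_datetime(times, utc=True),
                             "lat": lats, "lon": lons})

    def test_two_day_span_gives_midpoint(self):
        f = self._fixes(["2016-01-01 00:00", "2016-01-03 00:00"], [0.0, 0.0], [0.0, 10.0])
        rt = geodesy.regularize(f, "1D")
        assert len(rt.positions) == 3
        assert rt.positions["lon"].iloc[1] == pytest.approx(5.0, abs=1e-6)

    def test_already_daily_is_identity(self):
        f = self._fixes(pd.date_range("2016-01-01", periods=5, freq="1D", tz="UTC"),
                        [10, 11, 12, 13, 14], [100, 101, 102, 103, 104])
        rt = geodesy.regularize(f, "1D")
        np.testing.assert_allclose(rt.positions["lat"], f["lat"], atol=1e-9)
        np.testing.assert_allclose(rt.positions["lon"], f["lon"], atol=1e-9)

    def test_resampled_points_lie_on_polyline(self):
        rng = np.random.default_rng(3)
        times = pd.date_range("2016-04-01", periods=60, freq="2h", tz="UTC")
        lat = np.cumsum(rng.normal(0.05, 0.05, 60)) + 40
        lon = np.cumsum(rng.normal(0.08, 0.05, 60)) + 135
        f = self._fixes(times, lat, lon)
        rt = geodesy.regularize(f, "6h")
        for _, row in rt.positions.iterrows():
            d = min(
                _cross_track_km(row["lat"], row["lon"], lat[i], lon[i], lat[i + 1], lon[i + 1])
                for i in range(len(lat) - 1)
            )
            assert d < 1e-3  # within 1 m of the source polyline

    def test_never_extrapolates(self):
        f = self._fixes(["2016-01-01 03:00", "2016-01-04 21:00"], [0, 5], [0, 5])
        rt = geodesy.regularize(f, "1D")
        assert rt.positions["timestamp"].min() >= f["timestamp"].min()
        assert rt.positions["timestamp"].max() <= f["timestamp"].max()

    def test_regularized_path_no_longer_than_source(self):
        rng = np.random.default_rng(4)
        times = pd.date_range("2016-01-01", periods=40, freq="2h", tz="UTC")
        lat = np.cumsum(rng.normal(0, 0.2, 40)) + 50
        lon = np.cumsum(rng.normal(0, 0.2, 40)) + 140
        f = self._fixes(times, lat, lon)
        rt = geodesy.regularize(f, "7h")
        assert geodesy.path_length_km(rt.positions["lat"], rt.positions["lon"]) <= (
            geodesy.path_length_km(lat, lon) + 1e-9)

    def test_flags_long_gaps(self):
        f = self._fixes(["2016-01-01", "2016-01-02", "2016-01-20"], [0, 1, 2], [0, 1, 2])
        rt = geodesy.regularize(f, "1D")
        assert rt.positions["interpolated_gap"].any()
        assert not rt.positions["interpolated_gap"].iloc[0]


class TestLaea:
    def test_center_maps_to_origin(self):
        p = geodesy.LaeaProjection(52.0, 140.0)
        assert p.forward(52.0, 140.0) == (pytest.approx(0.0, abs=1e-9),) * 2

    def test_point_due_north(self):
        p = geodesy.LaeaProjection(52.0, 140.0)
        d = 100.0 / R  # radians along the meridian
        x, y = p.forward(52.0 + np.degrees(d), 140.0)
        assert x == pytest.approx(0.0, abs=1e-6)
        assert y == pytest.approx(100.0, abs=0.01)

    def test_roundtrip_within_one_meter(self):
        rng = np.random.default_rng(5)
        p = geodesy.LaeaProjection(52.0, 150.0)
        lat = rng.uniform(15, 85, 500)
        lon = rng.uniform(100, 200, 500)  # spans the antimeridian
        x, y = p.forward(lat, geodesy.wrap_lon(lon))
        la, lo = p.inverse(x, y)
        err = geodesy.great_circle_km(lat, geodesy.wrap_lon(lon), la, lo)
        assert np.max(err) < 1e-3

    def test_equal_area_of_one_degree_cell(self):
        p = geodesy.LaeaProjection(60.0, 150.0)
        corners = [(60, 150), (61, 150), (61, 151), (60, 151)]
        xy = [p.forward(*c) for c in corners]
        area = 0.0  # shoelace on the projected quadrilateral
        for i in range(4):
            x1, y1 = xy[i]
            x2, y2 = xy[(i + 1) % 4]
            area += x1 * y2 - x2 * y1
        area = abs(area) / 2
        # spherical-excess oracle for the lat-lon cell
        true = R**2 * np.radians(1.0) * (np.sin(np.radians(61)) - np.sin(np.radians(60)))
        assert area == pytest.approx(true, rel=1e-3)

    def test_local_distances_match_great_circle(self):
        rng = np.random.default_rng(6)
        p = geodesy.LaeaProjection(45.0, 135.0)
        lat = 45 + rng.uniform(-2, 2, 200)
        lon = 135 + rng.uniform(-3, 3, 200)
        x, y = p.forward(lat, lon)
        for i in range(0, 200, 10):
            gc = geodesy.great_circle_km(lat[i], lon[i], lat[i + 1], lon[i + 1])
            if gc == 0 or gc > 500:
                continue
            planar = np.hypot(x[i] - x[i + 1], y[i] - y[i + 1])
            assert planar == pytest.approx(gc, rel=0.01)

    def test_antipode_rejected(self):
        p = geodesy.LaeaProjection(52.0, 140.0)
        with pytest.raises(ValueError):
            p.forward(-52.0, -40.0)


class TestRegularTrackExport:
    def test_csv_and_geojson_roundtrip_fields(self, tmp_path):
        f = pd.DataFrame({
            "timestamp": pd.date_range("2016-01-01", periods=4, freq="1D", tz="UTC"),
            "lat": [10.0, 11.0, 12.0, 13.0], "lon": [100.0, 101.0, 102.0, 103.0]})
        rt = geodesy.regularize(f, "1D", bird_id="b7")
        csv_path = tmp_path / "rt.csv"
        geodesy.regular_track_to_csv(rt, csv_path)
        back = pd.read_csv(csv_path)
        assert back["bird_id"].unique().tolist() == ["b7"]
        np.testing.assert_allclose(back["lat"], f["lat"], atol=1e-6)

        gj_path = tmp_path / "rt.geojson"
        geodesy.regular_track_to_geojson(rt, gj_path)
        import json
        gj = json.loads(gj_path.read_text())
        line = gj["features"][0]["geometry"]
        assert line["type"] == "LineString"
        assert len(line["coordinates"]) == 4
        assert line["coordinates"][0] == [100.0, 10.0]  # lon, lat order
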