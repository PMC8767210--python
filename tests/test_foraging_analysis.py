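import numpy as np
import pandas as pd
import pytest

from mirounga import foraging_analysis as fa
from mirounga.geometry import haversine_km


def _hourly(n, lat0=37.0, dlat=0.01, speed=1.0):
    return pd.DataFrame(
        {
            "timestamp": pd.date_range("2010-01-01", periods=n, freq="h"),
            "lat": lat0 + dlat * np.arange(n),
            "lon": -140.0 + 0.0 * np.arange(n),
            "speed_kmh": np.full(n, float(speed)),
        }
    )


def _dives_at(hourly, hours, dtype="benthic_foraging"):
    return pd.DataFrame(
        {
            "mid_timestamp": [hourly["timestamp"].iloc[h] for h in hours],
            "dive_type": dtype,
            "max_depth_m": 300.0,
        }
    )


class TestDetectForagingLocations:
    def test_slow_plus_foraging_dive_flags(self):
        h = _hourly(5, speed=1.0)
        flags = fa.detect_foraging_locations(h, _dives_at(h, [2]))
        assert flags["is_foraging"].tolist() == [False, False, True, False, False]

    def test_slow_with_only_drift_dives_not_foraging(self):
        h = _hourly(5, speed=1.0)
        flags = fa.detect_foraging_locations(h, _dives_at(h, [2], dtype="drift"))
        assert not flags["is_foraging"].any()

    def test_fast_transit_with_foraging_dive_not_foraging(self):
        h = _hourly(5, speed=5.0)
        flags = fa.detect_foraging_locations(h, _dives_at(h, [2]))
        assert not flags["is_foraging"].any()

    def test_raising_speed_threshold_never_reduces_flags(self):
        rng = np.random.default_rng(0)
        h = _hourly(50)
        h["speed_kmh"] = rng.uniform(0, 6, 50)
        dives = _dives_at(h, list(range(0, 50, 3)))
        base = fa.detect_foraging_locations(h, dives).is_foraging.sum()
        wide = fa.detect_foraging_locations(
            h, dives, fa.ForagingParams(max_foraging_speed_kmh=4.0)
        ).is_foraging.sum()
        assert wide >= base

    def test_no_foraging_dives_means_no_flags(self):
        h = _hourly(10, speed=0.5)
        empty = pd.DataFrame(columns=["mid_timestamp", "dive_type", "max_depth_m"])
        assert not fa.detect_foraging_locations(h, empty)["is_foraging"].any()


class TestProportionTimeFeeding:
    @pytest.mark.parametrize("k,expected", [(100, 1.0), (0, 0.0), (53, 0.53)])
    def test_fraction_of_flagged_hours(self, k, expected):
        flags = pd.DataFrame({"is_foraging": [True] * k + [False] * (100 - k)})
        assert fa.proportion_time_feeding(flags) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fa.proportion_time_feeding(pd.DataFrame({"is_foraging": []}))


class TestTripTypology:
    def _flags(self, n_apex_forage, n_stray):
        # outbound 0..19 (increasing distance), apex 20..39, return 40..59
        lat = np.concatenate([
            37.0 + 0.1 * np.arange(20),
            np.full(20, 39.0),
            39.0 - 0.1 * np.arange(20),
        ])
        flags = np.zeros(60, dtype=bool)
        flags[20 : 20 + n_apex_forage] = True
        flags[:n_stray] = True  # stray foraging on the outbound leg
        return pd.DataFrame(
            {
                "timestamp": pd.date_range("2010-01-01", periods=60, freq="h"),
                "lat": lat,
                "lon": np.full(60, -140.0),
                "is_foraging": flags,
            }
        )

    def test_all_apex_feeding_is_focused(self):
        assert fa.classify_trip_typology(self._flags(15, 0), (37.0, -140.0)) == "focused"

    def test_six_stray_locations_is_throughout(self):
        assert fa.classify_trip_typology(self._flags(10, 6), (37.0, -140.0)) == "throughout"

    def test_exactly_four_strays_is_still_focused(self):
        assert fa.classify_trip_typology(self._flags(10, 4), (37.0, -140.0)) == "focused"

    def test_no_foraging_labelled_none(self):
        assert fa.classify_trip_typology(self._flags(0, 0), (37.0, -140.0)) == "none"


class TestEcoregion:
    def _regions(self):
        from shapely.geometry import box

        return {
            "north": box(-160.0, 40.0, -120.0, 60.0),
            "south": box(-160.0, 20.0, -120.0, 40.0),
            "west": box(-179.0, 20.0, -160.0, 60.0),
        }

    def _flags(self, lats, lons):
        return pd.DataFrame(
            {"lat": lats, "lon": lons, "is_foraging": [True] * len(lats)}
        )

    def test_dominant_region_wins(self):
        lats = [45.0] * 84 + [30.0] * 16
        assert fa.assign_ecoregion(self._flags(lats, [-140.0] * 100), self._regions()) == "north"

    def test_no_majority_is_multiple(self):
        lats = [45.0] * 40 + [30.0] * 35 + [45.0] * 25
        lons = [-140.0] * 40 + [-140.0] * 35 + [-170.0] * 25
        assert fa.assign_ecoregion(self._flags(lats, lons), self._regions()) == "multiple"

    def test_exactly_half_is_a_majority(self):
        lats = [45.0] * 50 + [30.0] * 25 + [45.0] * 25
        lons = [-140.0] * 50 + [-140.0] * 25 + [-170.0] * 25
        assert fa.assign_ecoregion(self._flags(lats, lons), self._regions()) == "north"

    def test_geojson_feature_collection_accepted(self):
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"name": "box"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[-150, 40], [-130, 40], [-130, 50], [-150, 50], [-150, 40]]],
                    },
                }
            ],
        }
        flags = self._flags([45.0, 45.0], [-140.0, -140.0])
        assert fa.assign_ecoregion(flags, gj) == "box"


class TestDistanceToShelf:
    shelf_lats = np.linspace(30.0, 50.0, 30)
    shelf_lons = np.full(30, -123.0)

    def test_point_on_isobath_is_zero(self):
        assert fa.distance_to_shelf(40.0, -123.0, self.shelf_lats, self.shelf_lons) < 1e-6

    def test_inshore_point_at_table_scale(self):
        # a point 33.5 km east of the isobath at 40 N
        dlon = 33.5 / (111.195 * np.cos(np.radians(40.0)))
        d = fa.distance_to_shelf(40.0, -123.0 + dlon, self.shelf_lats, self.shelf_lons)
        assert d == pytest.approx(33.5, rel=0.01)

    def test_matches_densified_brute_force(self):
        rng = np.random.default_rng(1)
        dense_lats = np.linspace(30.0, 50.0, 40000)
        dense_lons = np.full_like(dense_lats, -123.0)
        for _ in range(10):
            lat, lon = rng.uniform(32, 48), rng.uniform(-130, -118)
            d = fa.distance_to_shelf(lat, lon, self.shelf_lats, self.shelf_lons)
            brute = haversine_km(lat, lon, dense_lats, dense_lons).min()
            assert d == pytest.approx(brute, rel=1e-3)


class TestForagingArea:
    def _flags_xy(self, lats, lons):
        return pd.DataFrame({"lat": lats, "lon": lons, "is_foraging": True})

    def test_identical_points_give_small_kernel_footprint(self):
        flags = self._flags_xy([40.0] * 12, [-140.0] * 12)
        area = fa.foraging_area_km2(flags)
        assert 0 < area < 500.0

    def test_uniform_disc_area_within_15pct(self):
        rng = np.random.default_rng(3)
        R = 100.0  # km
        n = 4000
        r = R * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        lat = 40.0 + (r * np.sin(th)) / 111.195
        lon = -140.0 + (r * np.cos(th)) / (111.195 * np.cos(np.radians(40.0)))
        area = fa.foraging_area_km2(self._flags_xy(lat, lon))
        assert area == pytest.approx(0.95 * np.pi * R**2, rel=0.15)

    def test_fewer_than_ten_locations_undefined(self):
        assert np.isnan(fa.foraging_area_km2(self._flags_xy([40.0] * 5, [-140.0] * 5)))


class TestHabitat:
    def test_fully_on_shelf_is_coastal(self):
        assert fa.habitat_type(np.full(50, 10.0)) == "coastal"

    def test_fully_offshore_is_open_ocean(self):
        assert fa.habitat_type(np.full(50, 400.0)) == "open ocean"

    def test_mixed_is_coastal_open_ocean(self):
        d = np.concatenate([np.full(25, 10.0), np.full(25, 400.0)])
        assert fa.habitat_type(d) == "coastal/open ocean"


def test_trip_summaries_are_total_with_31_variables(processed):
    """Every deployment yields all 31 variables (or explicit NaN) + labels."""
    coh = processed["cohort"]
    geom = coh.config.geometry
    shelf_lats, shelf_lons = geom.shelf_polyline()
    rows = []
    for dep in coh.deployments:
        flags = fa.detect_foraging_locations(
            processed["hourly"][dep.deployment_id], processed["dives"][dep.deployment_id]
        )
        rows.append(
            fa.trip_summary(
                dep.deployment_id, dep.sex, dep.trip, flags,
                processed["dives"][dep.deployment_id],
                (geom.colony_lat, geom.colony_lon), shelf_lats, shelf_lons,
                geom.ecoregion_geojson(),
            )
        )
    table = fa.trip_summary_table(rows)
    assert len(fa.TRIP_SUMMARY_VARIABLES) == 31
    assert set(fa.TRIP_SUMMARY_VARIABLES) <= set(table.columns)
    props = table[["prop_transit", "prop_pelagic_foraging", "prop_drift", "prop_benthic_foraging"]]
    assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)
    assert table["proportion_time_feeding"].between(0, 1).all()
    # males forage on the shelf, females offshore, in this geography
    males = table[table["sex"] == "male"]
    females = table[table["sex"] == "female"]
    assert (males["shelf_distance_km"] < 40).all()
    assert (females["shelf_distance_km"] > 60).all()
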