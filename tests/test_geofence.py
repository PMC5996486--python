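"""Great-circle distances, POI loading, and fence membership."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tweetsurv.errors import POIFormatError, ValidationError
from tweetsurv.geofence import (
    EARTH_RADIUS_KM,
    GridIndex,
    POI,
    Radii,
    classify,
    classify_corpus,
    haversine_km,
    load_pois,
)
from tweetsurv.synthetic_data import _offset_point

from conftest import make_tweet


def law_of_cosines_km(lat1, lon1, lat2, lon2):
    """Independent spherical law-of-cosines distance oracle."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return EARTH_RADIUS_KM * math.acos(max(-1.0, min(1.0, c)))


class TestHaversine:
    def test_identical_points_are_zero(self):
        assert haversine_km(12.5, -70.0, 12.5, -70.0) == 0.0

    def test_one_degree_of_longitude_at_equator(self):
        expected = EARTH_RADIUS_KM * math.pi / 180.0  # 111.1949 km
        assert haversine_km(0, 0, 0, 1) == pytest.approx(expected, rel=1e-9)

    def test_antipodal_points_are_half_circumference(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, rel=1e-9
        )

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            haversine_km(91, 0, 0, 0)

    @given(
        lat1=st.floats(-90, 90), lon1=st.floats(-180, 180),
        lat2=st.floats(-90, 90), lon2=st.floats(-180, 180),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_metric_properties_hold_everywhere(self, lat1, lon1, lat2, lon2):
        d = haversine_km(lat1, lon1, lat2, lon2)
        assert 0.0 <= d <= math.pi * EARTH_RADIUS_KM * (1 + 1e-12)
        assert d == haversine_km(lat2, lon2, lat1, lon1)
        if (lat1, lon1) == (lat2, lon2):
            assert d == 0.0

    def test_symmetry_and_oracle_agreement_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            lat1, lat2 = rng.uniform(-89, 89, 2)
            lon1, lon2 = rng.uniform(-180, 180, 2)
            d = haversine_km(lat1, lon1, lat2, lon2)
            assert d == pytest.approx(haversine_km(lat2, lon2, lat1, lon1), rel=1e-12)
            oracle = law_of_cosines_km(lat1, lon1, lat2, lon2)
            if oracle > 0.001:  # law of cosines is ill-conditioned below ~1 m
                assert d == pytest.approx(oracle, rel=1e-6)


AIRPORT_CSV = """id,type,name,latitude_deg,longitude_deg
1,large_airport,Alpha Intl,40.0,-100.0
2,small_airport,Beta Field,41.0,-101.0
3,large_airport,Gamma Intl,42.0,-102.0
4,heliport,Delta Pad,43.0,-103.0
5,large_airport,Epsilon Intl,44.0,-104.0
6,closed,Zeta Old,45.0,-105.0
7,large_airport,Eta Intl,46.0,-106.0
8,small_airport,Theta Strip,47.0,-107.0
9,medium_airport,Iota Regional,48.0,-108.0
10,seaplane_base,Kappa Dock,49.0,-109.0
"""


class TestLoadPois:
    def test_class_filter_keeps_matching_rows(self, tmp_path):
        path = tmp_path / "airports.csv"
        path.write_text(AIRPORT_CSV)
        pois = load_pois(path, "airport", class_filter="large_airport")
        assert len(pois) == 4
        assert all(p.poi_class == "large_airport" for p in pois)

    def test_no_filter_keeps_all_valid_rows(self, tmp_path):
        path = tmp_path / "airports.csv"
        path.write_text(AIRPORT_CSV)
        assert len(load_pois(path, "airport")) == 10

    def test_blank_latitude_row_skipped(self, tmp_path):
        path = tmp_path / "airports.csv"
        path.write_text(
            "id,type,name,latitude_deg,longitude_deg\n"
            "1,large_airport,Good,40.0,-100.0\n"
            "2,large_airport,Bad,,-101.0\n"
        )
        pois = load_pois(path, "airport", class_filter="large_airport")
        assert [p.poi_id for p in pois] == ["1"]

    def test_missing_coordinate_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,type,name,latitude_deg\n1,hospital,H,40.0\n")
        with pytest.raises(POIFormatError):
            load_pois(path, "hospital")


def _poi(poi_id, kind, lat, lon):
    return POI(poi_id, kind, poi_id, lat, lon)


class TestClassify:
    def test_tweet_near_both_is_in_both_collections(self):
        airport = _poi("a", "airport", 40.0, -100.0)
        lat, lon = _offset_point(40.0, -100.0, 0.0, 2.0)  # 2 km north of airport
        hospital_lat, hospital_lon = _offset_point(lat, lon, math.pi / 2, 0.1)
        hospital = _poi("h", "hospital", hospital_lat, hospital_lon)
        mb = classify(make_tweet(lat=lat, lon=lon), [airport], [hospital])
        assert mb.in_airport and mb.in_hospital
        assert mb.collection_label == "both"

    def test_outside_both_radii_is_geolocated(self):
        airport = _poi("a", "airport", 40.0, -100.0)
        hospital = _poi("h", "hospital", 41.0, -100.0)
        lat, lon = _offset_point(40.0, -100.0, 0.0, 5.0)
        mb = classify(make_tweet(lat=lat, lon=lon), [airport], [hospital])
        assert not mb.in_airport and not mb.in_hospital
        assert mb.collection_label == "geolocated"

    def test_boundary_distance_is_inclusive(self):
        airport = _poi("a", "airport", 40.0, -100.0)
        lat, lon = _offset_point(40.0, -100.0, 1.1, 3.0)
        tweet = make_tweet(lat=lat, lon=lon)
        d = haversine_km(lat, lon, airport.lat, airport.lon)
        assert d == pytest.approx(3.0, abs=1e-9)
        # fence radius set to the exact distance: membership at equality
        mb = classify(tweet, [airport], [], Radii(airport_km=d))
        assert mb.in_airport
        assert not classify(
            tweet, [airport], [], Radii(airport_km=d * (1 - 1e-12))
        ).in_airport

    def test_empty_poi_lists_mean_infinite_distance(self):
        mb = classify(make_tweet(), [], [])
        assert not mb.in_airport and not mb.in_hospital
        assert math.isinf(mb.nearest_airport_km)

    def test_membership_biconditional_with_radii(self):
        airport = _poi("a", "airport", 40.0, -100.0)
        radii = Radii()
        for d in (0.5, 2.9, 3.0, 3.1, 10.0):
            lat, lon = _offset_point(40.0, -100.0, 2.0, d)
            mb = classify(make_tweet(lat=lat, lon=lon), [airport], [])
            assert mb.in_airport == (mb.nearest_airport_km <= radii.airport_km)

    def test_enlarging_radius_never_shrinks_membership(self):
        rng = np.random.default_rng(7)
        airports = [_poi(f"a{i}", "airport", 40 + i, -100 - i) for i in range(3)]
        tweets = [
            make_tweet(f"t{i}", lat=float(rng.uniform(38, 45)), lon=float(rng.uniform(-105, -98)))
            for i in range(50)
        ]
        members_small = {
            m.tweet_id
            for m in classify_corpus(tweets, airports, [], Radii(airport_km=3))
            if m.in_airport
        }
        members_big = {
            m.tweet_id
            for m in classify_corpus(tweets, airports, [], Radii(airport_km=50))
            if m.in_airport
        }
        assert members_small <= members_big

    def test_vectorized_path_matches_scalar_path(self, sim_study):
        sample = sim_study.tweets[:200]
        vec = classify_corpus(sample, sim_study.airports, sim_study.hospitals)
        for t, mb in zip(sample, vec):
            one = classify(t, sim_study.airports, sim_study.hospitals)
            assert (one.in_airport, one.in_hospital) == (mb.in_airport, mb.in_hospital)
            assert one.nearest_airport_km == pytest.approx(
                mb.nearest_airport_km, rel=1e-9, abs=1e-12
            )


class TestGridIndex:
    def test_matches_brute_force_nearest(self, sim_study):
        index = GridIndex(sim_study.airports, cell_deg=1.0)
        brute = classify_corpus(sim_study.tweets[:300], sim_study.airports, [])
        for t, mb in zip(sim_study.tweets[:300], brute):
            assert index.nearest_km(t.lat, t.lon) == pytest.approx(
                mb.nearest_airport_km, rel=1e-9
            )

    def test_empty_index_returns_infinity(self):
        assert math.isinf(GridIndex([]).nearest_km(0, 0))
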