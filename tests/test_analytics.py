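"""Collection summaries, term distributions, common terms, GeoJSON export."""

import json

import pytest

import tweetsurv as ts
from tweetsurv.errors import ValidationError
from tweetsurv.geofence import CollectionMembership
from tweetsurv.matcher import Mention
from tweetsurv.analytics import (
    CollectionSummary,
    common_terms,
    export_geo,
    summarize_collections,
    term_distribution,
)

from conftest import make_tweet


def _membership(tweet_id, in_airport=False, in_hospital=False):
    return CollectionMembership(tweet_id, in_airport, in_hospital, 99.0, 99.0)


def _mention(tweet_id, canonical):
    return Mention(tweet_id, canonical, canonical, 0, len(canonical), False)


def _memberships(n_airport_only, n_hospital_only, n_both, n_geo):
    out, i = [], 0
    for _ in range(n_airport_only):
        out.append(_membership(f"t{i}", in_airport=True)); i += 1
    for _ in range(n_hospital_only):
        out.append(_membership(f"t{i}", in_hospital=True)); i += 1
    for _ in range(n_both):
        out.append(_membership(f"t{i}", in_airport=True, in_hospital=True)); i += 1
    for _ in range(n_geo):
        out.append(_membership(f"t{i}")); i += 1
    return out


class TestSummarizeCollections:
    def test_overlap_accounting_of_reference_counts(self):
        s = summarize_collections(_memberships(239, 129, 3, 10242))
        assert (s.n_airport, s.n_hospital, s.n_overlap, s.n_geolocated) == (
            242, 132, 3, 10242,
        )
        assert s.n_unique_total == 10613

    def test_empty_input_is_all_zeros(self):
        s = summarize_collections([])
        assert s == CollectionSummary(0, 0, 0, 0, 0)

    def test_identity_violation_rejected(self):
        with pytest.raises(ValidationError):
            CollectionSummary(2, 2, 1, 5, 9)

    def test_overlap_bounded_by_collection_sizes(self):
        with pytest.raises(ValidationError):
            CollectionSummary(1, 5, 2, 0, 4)

    def test_matches_generator_ground_truth(self, sim_study):
        s = sim_study.result.summary
        truth_counts = {"airport": 0, "hospital": 0, "geolocated": 0}
        mention_ids = set(sim_study.result.mentions_by_tweet)
        for r in sim_study.truth.records.values():
            if r.tweet_id in mention_ids:
                truth_counts[r.collection] += 1
        assert s.n_airport == truth_counts["airport"]
        assert s.n_hospital == truth_counts["hospital"]
        assert s.n_geolocated == truth_counts["geolocated"]
        assert s.n_overlap == 0  # POIs are placed >= 10 km apart


class TestTermDistribution:
    def _inputs(self):
        mentions = {}
        memberships = []
        # "ague" in 3 geolocated tweets, "colic" in 1
        for i in range(3):
            mentions[f"g{i}"] = [_mention(f"g{i}", "ague")]
            memberships.append(_membership(f"g{i}"))
        mentions["g9"] = [_mention("g9", "colic")]
        memberships.append(_membership("g9"))
        return mentions, memberships

    def test_count_at_threshold_retained(self):
        mentions = {f"t{i}": [_mention(f"t{i}", "ague")] for i in range(30)}
        memberships = [_membership(f"t{i}") for i in range(30)]
        dist = term_distribution(mentions, memberships, "geolocated", threshold=30)
        assert list(dist.rows["count"]) == [30]
        assert dist.n_omitted == 0

    def test_all_below_threshold_all_omitted(self):
        mentions, memberships = self._inputs()
        dist = term_distribution(mentions, memberships, "geolocated", threshold=5)
        assert len(dist.rows) == 0
        assert dist.n_omitted == 2

    def test_counts_are_per_tweet_not_per_occurrence(self):
        mentions = {"t0": [_mention("t0", "ague"), _mention("t0", "ague")]}
        dist = term_distribution(mentions, [_membership("t0")], "geolocated")
        assert list(dist.rows["count"]) == [1]

    def test_unknown_collection_rejected(self):
        with pytest.raises(ValidationError):
            term_distribution({}, [], "seaport")

    def test_descending_counts_with_term_tiebreak(self):
        mentions, memberships = self._inputs()
        dist = term_distribution(mentions, memberships, "geolocated")
        assert list(dist.rows["term"]) == ["ague", "colic"]
        assert list(dist.rows["count"]) == [3, 1]

    def test_planted_term_count_recovered_exactly(self, sim_study):
        """Every planted term's distribution count equals the generator's."""
        dist = term_distribution(
            sim_study.result.mentions_by_tweet, sim_study.result.memberships, "all"
        )
        mention_ids = set(sim_study.result.mentions_by_tweet)
        planted_counts = {}
        for r in sim_study.truth.records.values():
            if r.term and r.tweet_id in mention_ids:
                planted_counts[r.term] = planted_counts.get(r.term, 0) + 1
        assert dict(zip(dist.rows["term"], dist.rows["count"])) == planted_counts


class TestCommonTerms:
    def _dist(self, collection, counts):
        mentions, memberships = {}, []
        i = 0
        flags = {
            "airport": {"in_airport": True},
            "hospital": {"in_hospital": True},
            "geolocated": {},
        }[collection]
        for term, count in counts.items():
            for _ in range(count):
                tid = f"{collection}{i}"; i += 1
                mentions[tid] = [_mention(tid, term)]
                memberships.append(_membership(tid, **flags))
        return term_distribution(mentions, memberships, collection)

    def test_intersection_of_planted_shared_terms(self):
        d1 = self._dist("airport", {"ague": 2, "colic": 1, "croup": 4, "gout": 1})
        d2 = self._dist("hospital", {"ague": 1, "colic": 2, "croup": 2, "pox": 3})
        d3 = self._dist("geolocated", {"ague": 9, "colic": 3, "croup": 1})
        report = common_terms([d1, d2, d3])
        assert report.common == {"ague", "colic", "croup"}

    def test_rare_intersection_uses_per_collection_cutoffs(self):
        d1 = self._dist("airport", {"ague": 2, "croup": 12})
        d2 = self._dist("hospital", {"ague": 1, "croup": 2})
        d3 = self._dist("geolocated", {"ague": 9, "croup": 11})
        report = common_terms([d1, d2, d3])
        # hospital cutoff 5 admits croup(2); airport/geolocated cutoff 10 does not
        assert report.rare_common == {"ague"}

    def test_disjoint_distributions_share_nothing(self):
        d1 = self._dist("airport", {"ague": 1})
        d2 = self._dist("hospital", {"pox": 1})
        assert common_terms([d1, d2]).common == set()

    def test_empty_collection_empties_the_intersection(self):
        d1 = self._dist("airport", {"ague": 1})
        d2 = self._dist("hospital", {})
        assert common_terms([d1, d2]).common == set()

    def test_single_distribution_rejected(self):
        with pytest.raises(ValidationError):
            common_terms([self._dist("airport", {"ague": 1})])


class TestExportGeo:
    def _fixture(self):
        tweets = [make_tweet(f"t{i}", text="ague case", lat=10.0 + i * 0.1,
                             lon=-70.123456 + i) for i in range(5)]
        mentions = {t.tweet_id: [_mention(t.tweet_id, "ague")] for t in tweets}
        memberships = [_membership(t.tweet_id, in_airport=(t.tweet_id == "t0"))
                       for t in tweets]
        return tweets, mentions, memberships

    def test_one_point_feature_per_mention_tweet(self, tmp_path):
        tweets, mentions, memberships = self._fixture()
        fc = export_geo(tweets, mentions, memberships)
        assert fc["type"] == "FeatureCollection"
        assert len(fc["features"]) == 5
        assert all(f["geometry"]["type"] == "Point" for f in fc["features"])

    def test_coordinates_are_lon_lat_ordered(self):
        tweets, mentions, memberships = self._fixture()
        fc = export_geo(tweets, mentions, memberships)
        lon, lat = fc["features"][0]["geometry"]["coordinates"]
        assert lon == pytest.approx(tweets[0].lon, abs=1e-6)
        assert lat == pytest.approx(tweets[0].lat, abs=1e-6)

    def test_round_trip_preserves_coordinates_to_six_decimals(self, tmp_path):
        tweets, mentions, memberships = self._fixture()
        path = tmp_path / "out.geojson"
        export_geo(tweets, mentions, memberships, path)
        fc = json.loads(path.read_text())
        for t, f in zip(tweets, fc["features"]):
            lon, lat = f["geometry"]["coordinates"]
            assert lon == pytest.approx(t.lon, abs=5e-7)
            assert lat == pytest.approx(t.lat, abs=5e-7)

    def test_mention_free_tweets_excluded(self):
        tweets, mentions, memberships = self._fixture()
        tweets.append(make_tweet("t9", text="no terms here"))
        fc = export_geo(tweets, mentions, memberships)
        assert len(fc["features"]) == 5
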