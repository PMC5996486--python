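"""Result surfaces: collection summaries, term distributions, geographic export.

Counting conventions: frequencies are per-tweet (a term is counted once per
tweet however often it recurs in the text), and a tweet inside both the
airport and the hospital fence contributes to both collections' counts —
the summary identity ``n_unique = n_airport + n_hospital - n_overlap +
n_geolocated`` keeps the accounting honest.  Omission thresholds follow the
"terms appearing in fewer than k messages are omitted" convention: retained
rows satisfy ``count >= threshold``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import FilterResult, NoiseRuleSet, Tweet, filter_corpus
from .errors import ValidationError
from .geofence import POI, CollectionMembership, Radii, classify_corpus
from .lexicon import DiseaseLexicon
from .matcher import Mention, find_corpus_mentions
from .ner_agreement import (
    AgreementReport,
    LexiconIdentifier,
    agreement_score,
    identify_corpus,
    mean_relevance,
)
from .pos_patterns import PennRuleTagger, Tagger, generate_patterns, normalize_text, tag

COLLECTIONS = ("airport", "hospital", "geolocated")


@dataclass(frozen=True)
class CollectionSummary:
    """Mention-bearing tweet counts per collection, with overlap."""

    n_airport: int
    n_hospital: int
    n_overlap: int
    n_geolocated: int
    n_unique_total: int

    def __post_init__(self) -> None:
        if self.n_unique_total != (
            self.n_airport + self.n_hospital - self.n_overlap + self.n_geolocated
        ):
            raise ValidationError("collection summary identity violated")
        if self.n_overlap > min(self.n_airport, self.n_hospital):
            raise ValidationError("overlap exceeds a collection size")


def summarize_collections(
    memberships: Iterable[CollectionMembership],
) -> CollectionSummary:
    """Aggregate fence memberships of the mention-bearing tweets."""
    n_airport = n_hospital = n_overlap = n_geo = n_unique = 0
    for mb in memberships:
        n_unique += 1
        if mb.in_airport:
            n_airport += 1
        if mb.in_hospital:
            n_hospital += 1
        if mb.in_airport and mb.in_hospital:
            n_overlap += 1
        if not mb.in_airport and not mb.in_hospital:
            n_geo += 1
    return CollectionSummary(n_airport, n_hospital, n_overlap, n_geo, n_unique)


@dataclass
class TermDistribution:
    """Ranked per-term tweet counts for one collection."""

    collection: str
    rows: pd.DataFrame  # columns: term, count (descending)
    threshold: int
    n_omitted: int

    @property
    def terms(self) -> set[str]:
        return set(self.rows["term"])


def _tweets_in_collection(
    memberships: Iterable[CollectionMembership], collection: str
) -> set[str]:
    if collection == "airport":
        return {m.tweet_id for m in memberships if m.in_airport}
    if collection == "hospital":
        return {m.tweet_id for m in memberships if m.in_hospital}
    if collection == "geolocated":
        return {m.tweet_id for m in memberships if not m.in_airport and not m.in_hospital}
    if collection == "all":
        return {m.tweet_id for m in memberships}
    raise ValidationError(f"unknown collection {collection!r}")


def term_distribution(
    mentions_by_tweet: Mapping[str, Sequence[Mention]],
    memberships: Sequence[CollectionMembership],
    collection: str,
    threshold: int = 0,
) -> TermDistribution:
    """Per-term tweet counts within a collection, descending.

    Terms seen in fewer than *threshold* tweets are omitted from the rows
    and tallied in ``n_omitted``.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    member_ids = _tweets_in_collection(memberships, collection)
    counts: dict[str, int] = {}
    for tweet_id in member_ids:
        for canonical in {m.canonical for m in mentions_by_tweet.get(tweet_id, ())}:
            counts[canonical] = counts.get(canonical, 0) + 1
    kept = [(t, c) for t, c in counts.items() if c >= threshold]
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    rows = pd.DataFrame(kept, columns=["term", "count"])
    return TermDistribution(
        collection=collection,
        rows=rows,
        threshold=threshold,
        n_omitted=len(counts) - len(kept),
    )


@dataclass
class CommonTermsReport:
    """Cross-collection term-set comparison."""

    common: set[str]  # terms present in every collection
    rare_by_collection: dict[str, set[str]]  # per-collection low-frequency terms
    rare_common: set[str]  # rare terms shared by all collections


def common_terms(
    distributions: Sequence[TermDistribution],
    rare_cutoffs: Mapping[str, int] | None = None,
) -> CommonTermsReport:
    """Intersection of collection term sets, plus rare-term intersections.

    ``rare_cutoffs`` maps collection label to a count *c*: a term is rare
    there when its count is strictly below *c* (defaults: geolocated 10,
    airport 10, hospital 5).  Pass unthresholded distributions, otherwise
    omitted terms cannot participate.
    """
    if len(distributions) < 2:
        raise ValidationError("need at least two distributions to compare")
    if rare_cutoffs is None:
        rare_cutoffs = {"geolocated": 10, "airport": 10, "hospital": 5}
    term_sets = [d.terms for d in distributions]
    common = set.intersection(*term_sets)
    rare_by_collection: dict[str, set[str]] = {}
    for d in distributions:
        cutoff = rare_cutoffs.get(d.collection, 10)
        rare_by_collection[d.collection] = {
            t for t, c in zip(d.rows["term"], d.rows["count"]) if c < cutoff
        }
    rare_common = (
        set.intersection(*rare_by_collection.values()) if rare_by_collection else set()
    )
    return CommonTermsReport(common, rare_by_collection, rare_common)


def export_geo(
    tweets: Sequence[Tweet],
    mentions_by_tweet: Mapping[str, Sequence[Mention]],
    memberships: Sequence[CollectionMembership],
    path: str | Path | None = None,
) -> dict:
    """GeoJSON FeatureCollection of mention-bearing tweets.

    One Point feature per tweet with coordinates ``(lon, lat)`` rounded to
    6 decimals and properties carrying the collection flags and canonical
    terms.  Returns the FeatureCollection dict; writes it when *path* is
    given.
    """
    mb_by_id = {m.tweet_id: m for m in memberships}
    features = []
    for t in tweets:
        if t.tweet_id not in mentions_by_tweet:
            continue
        mb = mb_by_id.get(t.tweet_id)
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [round(t.lon, 6), round(t.lat, 6)],
                },
                "properties": {
                    "tweet_id": t.tweet_id,
                    "terms": sorted({m.canonical for m in mentions_by_tweet[t.tweet_id]}),
                    "in_airport": bool(mb.in_airport) if mb else False,
                    "in_hospital": bool(mb.in_hospital) if mb else False,
                    "collection": mb.collection_label if mb else "geolocated",
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(collection, fh, ensure_ascii=False)
    return collection


@dataclass
class PipelineResult:
    """Everything one end-to-end run produces."""

    filter_result: FilterResult
    mentions_by_tweet: dict[str, list[Mention]]
    memberships: list[CollectionMembership]  # mention-bearing tweets only
    summary: CollectionSummary
    distributions: dict[str, TermDistribution]
    pattern_tables: dict[str, pd.DataFrame]
    agreement: AgreementReport
    mean_scores: dict[str, float]
    mean_scores_all_tweets: dict[str, float]
    mention_tweets: list[Tweet] = field(default_factory=list)


def run_pipeline(
    tweets: Sequence[Tweet],
    lexicon: DiseaseLexicon,
    airports: Sequence[POI],
    hospitals: Sequence[POI],
    rules: NoiseRuleSet | None = None,
    radii: Radii = Radii(),
    tagger: Tagger | None = None,
    thresholds: Mapping[str, int] | None = None,
    pattern_min_count: int = 1,
) -> PipelineResult:
    """Run the whole analysis on an in-memory corpus.

    Stages: noise filtering -> dictionary matching -> geofencing of the
    mention-bearing tweets -> per-collection term distributions and POS
    pattern tables -> stand-in concept identification and agreement.
    """
    if tagger is None:
        tagger = PennRuleTagger()
    if thresholds is None:
        thresholds = {"hospital": 1, "airport": 2, "geolocated": 30}
    filtered = filter_corpus(tweets, rules)
    mentions_by_tweet = find_corpus_mentions(filtered.kept, lexicon)
    mention_tweets = [t for t in filtered.kept if t.tweet_id in mentions_by_tweet]
    memberships = classify_corpus(mention_tweets, airports, hospitals, radii)
    summary = summarize_collections(memberships)
    distributions = {
        c: term_distribution(mentions_by_tweet, memberships, c, thresholds.get(c, 0))
        for c in COLLECTIONS
    }
    # POS patterns per collection, normalizing on each tweet's first mention
    member_ids = {c: _tweets_in_collection(memberships, c) for c in COLLECTIONS}
    patterns: dict[str, list] = {c: [] for c in COLLECTIONS}
    for t in mention_tweets:
        first = mentions_by_tweet[t.tweet_id][0]
        tagged = tag(normalize_text(t.text, first), tagger)
        tweet_patterns = generate_patterns(tagged)
        for c in COLLECTIONS:
            if t.tweet_id in member_ids[c]:
                patterns[c].extend(tweet_patterns)
    from .pos_patterns import pattern_frequencies

    pattern_tables = {
        c: pattern_frequencies(patterns[c], min_count=pattern_min_count)
        for c in COLLECTIONS
    }
    identifier = LexiconIdentifier(lexicon)
    hits_by_tweet = identify_corpus(mention_tweets, identifier)
    agreement = agreement_score(hits_by_tweet, mentions_by_tweet)
    mean_scores = mean_relevance(hits_by_tweet, memberships)
    mean_scores_all = mean_relevance(hits_by_tweet, memberships, over_all_tweets=True)
    return PipelineResult(
        filter_result=filtered,
        mentions_by_tweet=mentions_by_tweet,
        memberships=memberships,
        summary=summary,
        distributions=distributions,
        pattern_tables=pattern_tables,
        agreement=agreement,
        mean_scores=mean_scores,
        mean_scores_all_tweets=mean_scores_all,
        mention_tweets=mention_tweets,
    )


def write_run(
    result: PipelineResult,
    outdir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> Path:
    """Write TSV/GeoJSON reports plus a provenance manifest to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c, dist in result.distributions.items():
        dist.rows.to_csv(outdir / f"terms_{c}.tsv", sep="\t", index=False)
    for c, table in result.pattern_tables.items():
        table.to_csv(outdir / f"patterns_{c}.tsv", sep="\t", index=False)
    export_geo(
        result.mention_tweets,
        result.mentions_by_tweet,
        result.memberships,
        outdir / "tweets.geojson",
    )
    manifest = {
        "seed": seed,
        "config": dict(config) if config else None,
        "counts": {
            "kept": len(result.filter_result.kept),
            "noise_job": len(result.filter_result.noise_job),
            "noise_checkin": len(result.filter_result.noise_checkin),
            "mention_tweets": len(result.mention_tweets),
            "airport": result.summary.n_airport,
            "hospital": result.summary.n_hospital,
            "overlap": result.summary.n_overlap,
            "geolocated": result.summary.n_geolocated,
            "unique_total": result.summary.n_unique_total,
        },
        "agreement": result.agreement.agreement_reported,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
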