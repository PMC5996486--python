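"""Synthetic geolocated corpora with full ground truth.

The generator emulates the statistical structure the analysis assumes
rather than linguistic realism: a minority of *news* tweets that repeat a
small pool of headline texts verbatim (each embedding a frequent disease
term), *personal* tweets that embed a term drawn from a long catalog tail,
job-ad / check-in *noise* instantiating the default filter patterns, and
disease-free *background* chatter.  Coordinates are sampled either within
the scatter radius of a point of interest (airport or hospital) or
uniformly in the study region outside every fence, by exact spherical
offset, so the planted collection labels agree with the haversine fences
by construction.

Every tweet carries a ground-truth record (class, planted term, planted
collection) so each pipeline stage can be scored against what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Tweet
from .errors import ValidationError
from .geofence import EARTH_RADIUS_KM, POI, CollectionMembership, Radii, haversine_km

_MODIFIERS = (
    "viral", "chronic", "acute", "renal", "cardiac", "hepatic", "spinal",
    "gastric", "febrile", "cystic", "ocular", "dermal", "neural", "septic",
    "fungal", "nasal", "oral", "lumbar", "cranial", "vascular",
)
_NOUNS = (
    "fever", "rash", "infection", "fatigue", "atrophy", "palsy", "anemia",
    "edema", "sepsis", "ulcer", "asthma", "eczema", "tremor", "vertigo",
    "neuralgia",
)

_PLACES = (
    "Springfield", "Riverton", "Lakeside", "Hilltown", "Porton",
    "Greenville", "Easton", "Weston", "Milbrook", "Fairview",
)
_VENUES = (
    "Coffee Corner", "Central Plaza", "Sunset Diner", "Harbor House",
    "Summit Lounge",
)
_HANDLES = ("sam_k", "jordan22", "rj_walker", "casey_m", "drpatel")

_PERSONAL_TEMPLATES = (
    "I have {term} again",
    "my {term} is acting up",
    "dealing with {term} today",
    "this {term} is awful",
    "I think I have {term}",
    "recovering from {term} slowly",
    "my doctor says it is {term}",
    "cannot sleep because of {term}",
    "week two living with {term}",
    "hate having {term}",
    "battling {term} since monday",
    "my {term} flared up during dinner",
    "still stuck home with {term}",
    "finally over my {term}",
    "told I might have {term} waiting on tests",
    "{term} ruined my weekend",
    "why does {term} happen to me",
    "honestly {term} is exhausting",
    "anyone else coping with {term}?",
    "@{handle} I have {term} again!",
)

_NEWS_TEMPLATES = (
    "{term} outbreak reported in {place} http://news.example/{k}",
    "Health officials warn of {term} cases in {place} http://news.example/{k}",
    "{place} clinic sees rise in {term} http://news.example/{k}",
    "New report links {term} to travel through {place} http://news.example/{k}",
    "Experts track {term} cluster near {place} http://news.example/{k}",
)

_JOB_TEMPLATES = (
    "We're #hiring! Read about our latest #job opening here: {place} General Seeking Multiple Specialties",
    "Great #job opening in {place}, apply now",
)
_CHECKIN_TEMPLATES = (
    "I'm at {venue} in {place}",
)

_BACKGROUND_TEMPLATES = (
    "what a lovely morning in {place}",
    "traffic is terrible today",
    "watching the game tonight with friends",
    "baked bread for the first time and it worked",
    "cannot believe how windy it got",
    "new playlist on repeat all day",
    "meeting ran long again",
    "sunset over {place} was stunning",
    "finally finished that book",
    "coffee first, everything else later",
    "weekend plans: absolutely nothing",
    "the queue at the bakery wrapped around the block",
    "lost my umbrella on the bus again",
    "movie night was a success",
    "planted tomatoes this afternoon",
)

CLASS_NEWS = "news"
CLASS_PERSONAL = "personal"
CLASS_NOISE = "noise"
CLASS_BACKGROUND = "background"


def default_term_catalog() -> tuple[tuple[str, float], ...]:
    """300 two-word disease terms with uniform relative prevalence.

    Built as modifier x noun products ("viral fever", "renal edema", ...);
    no term is a token subsequence of another, so strict matching is
    unambiguous.
    """
    return tuple((f"{m} {n}", 1.0) for m in _MODIFIERS for n in _NOUNS)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults are the study conditions.

    Class proportions: ``frac_news`` news-duplicate tweets, ``frac_noise``
    job-ad/check-in noise, ``frac_mention`` personal tweets embedding a
    disease term, remainder disease-free background.  ``news_dup_factor``
    is the mean number of verbatim copies per news title.  News titles
    draw their terms from the first ``news_head_frac`` of the catalog;
    personal tweets draw from the rest, weighted by catalog prevalence.
    """

    seed: int = 0
    n_tweets: int = 5000
    frac_news: float = 0.20
    news_dup_factor: float = 20.0
    frac_noise: float = 0.10
    frac_mention: float = 0.25
    p_airport: float = 0.05
    p_hospital: float = 0.04
    airport_scatter_km: float = 1.0
    hospital_scatter_km: float = 0.1
    radii: Radii = field(default_factory=Radii)
    term_catalog: tuple[tuple[str, float], ...] = field(default_factory=default_term_catalog)
    news_head_frac: float = 0.10
    lang: str = "en"

    def __post_init__(self) -> None:
        for name in ("frac_news", "frac_noise", "frac_mention", "p_airport", "p_hospital"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_news + self.frac_noise + self.frac_mention > 1.0 + 1e-9:
            raise ValidationError("class proportions exceed 1")
        if self.news_dup_factor < 1.0:
            raise ValidationError("news_dup_factor must be >= 1")
        if (self.frac_mention > 0 or self.frac_news > 0) and not self.term_catalog:
            raise ValidationError("term_catalog empty but mention/news tweets requested")

    @property
    def head_terms(self) -> tuple[str, ...]:
        n_head = max(1, round(self.news_head_frac * len(self.term_catalog)))
        return tuple(t for t, _w in self.term_catalog[:n_head])

    @property
    def tail_terms(self) -> tuple[tuple[str, float], ...]:
        n_head = max(1, round(self.news_head_frac * len(self.term_catalog)))
        tail = self.term_catalog[n_head:]
        return tail if tail else self.term_catalog


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated tweet."""

    tweet_id: str
    cls: str  # news | personal | noise | background
    term: str | None
    collection: str  # airport | hospital | geolocated


@dataclass
class GroundTruth:
    """Per-tweet ground truth for a generated corpus."""

    records: dict[str, TruthRecord]

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("tweet_id\tclass\tterm\tcollection\n")
            for r in self.records.values():
                fh.write(f"{r.tweet_id}\t{r.cls}\t{r.term or ''}\t{r.collection}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        records = {}
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                tweet_id, c, term, collection = line.rstrip("\n").split("\t")
                records[tweet_id] = TruthRecord(tweet_id, c, term or None, collection)
        return cls(records)


# -- geometry -----------------------------------------------------------------

# Study region: a mid-latitude box, far from poles and dateline.
_REGION_LAT = (25.0, 48.0)
_REGION_LON = (-115.0, -75.0)


def _offset_point(lat: float, lon: float, bearing_rad: float, dist_km: float) -> tuple[float, float]:
    """Destination point at a bearing/distance on the R=6371 km sphere."""
    delta = dist_km / EARTH_RADIUS_KM
    phi1 = math.radians(lat)
    lam1 = math.radians(lon)
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta)
        + math.cos(phi1) * math.sin(delta) * math.cos(bearing_rad)
    )
    lam2 = lam1 + math.atan2(
        math.sin(bearing_rad) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    lon2 = (math.degrees(lam2) + 540.0) % 360.0 - 180.0
    return math.degrees(phi2), lon2


def generate_pois(
    n_airports: int,
    n_hospitals: int,
    seed: int,
    min_separation_km: float = 10.0,
    max_tries: int = 10000,
) -> tuple[list[POI], list[POI]]:
    """Place airports and hospitals uniformly in the study region.

    All POIs (across kinds) are at least ``min_separation_km`` apart so the
    3 km / 0.2 km fences never overlap; if the requested density cannot be
    placed a :class:`ValidationError` is raised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    placed: list[tuple[float, float]] = []

    def sample_one() -> tuple[float, float]:
        for _ in range(max_tries):
            lat = float(rng.uniform(*_REGION_LAT))
            lon = float(rng.uniform(*_REGION_LON))
            if all(haversine_km(lat, lon, a, b) >= min_separation_km for a, b in placed):
                placed.append((lat, lon))
                return lat, lon
        raise ValidationError(
            f"cannot place POIs {min_separation_km} km apart in the study region"
        )

    airports = []
    for i in range(n_airports):
        lat, lon = sample_one()
        airports.append(POI(f"AP{i:03d}", "airport", f"Airport {i}", lat, lon, "large_airport"))
    hospitals = []
    for i in range(n_hospitals):
        lat, lon = sample_one()
        hospitals.append(POI(f"HO{i:03d}", "hospital", f"Hospital {i}", lat, lon, "hospital"))
    return airports, hospitals


def _sample_location(
    cfg: SimConfig,
    rng: np.random.Generator,
    airports: Sequence[POI],
    hospitals: Sequence[POI],
) -> tuple[float, float, str]:
    """Coordinates plus the planted collection label."""
    u = rng.random()
    if airports and u < cfg.p_airport:
        poi = airports[rng.integers(len(airports))]
        lat, lon = _offset_point(
            poi.lat, poi.lon, rng.uniform(0, 2 * math.pi),
            float(rng.uniform(0, cfg.airport_scatter_km)),
        )
        return lat, lon, "airport"
    if hospitals and u < cfg.p_airport + cfg.p_hospital:
        poi = hospitals[rng.integers(len(hospitals))]
        lat, lon = _offset_point(
            poi.lat, poi.lon, rng.uniform(0, 2 * math.pi),
            float(rng.uniform(0, cfg.hospital_scatter_km)),
        )
        return lat, lon, "hospital"
    # background: uniform in the region, outside every fence
    for _ in range(1000):
        lat = float(rng.uniform(*_REGION_LAT))
        lon = float(rng.uniform(*_REGION_LON))
        near_airport = any(
            haversine_km(lat, lon, p.lat, p.lon) <= cfg.radii.airport_km for p in airports
        )
        near_hospital = any(
            haversine_km(lat, lon, p.lat, p.lon) <= cfg.radii.hospital_km for p in hospitals
        )
        if not near_airport and not near_hospital:
            return lat, lon, "geolocated"
    raise ValidationError("could not sample a background location outside all fences")


def generate_corpus(
    cfg: SimConfig,
    airports: Sequence[POI],
    hospitals: Sequence[POI],
) -> tuple[list[Tweet], GroundTruth]:
    """Generate a corpus and its ground truth (deterministic in cfg.seed).

    News titles are built round-robin over the catalog head so every head
    term is covered, and each title is copied ``news_dup_factor`` times on
    average; personal tweets draw terms from the catalog tail with the
    configured prevalences.
    """
    ss = np.random.SeedSequence([cfg.seed, 7])
    rng_class, rng_text, rng_geo = (np.random.default_rng(s) for s in ss.spawn(3))

    n = cfg.n_tweets
    classes = rng_class.choice(
        [CLASS_NEWS, CLASS_NOISE, CLASS_PERSONAL, CLASS_BACKGROUND],
        size=n,
        p=[
            cfg.frac_news,
            cfg.frac_noise,
            cfg.frac_mention,
            1.0 - cfg.frac_news - cfg.frac_noise - cfg.frac_mention,
        ],
    )
    n_news = int(np.sum(classes == CLASS_NEWS))

    # fixed title pool: round-robin terms over titles, copies spread evenly
    n_titles = max(1, round(n_news / cfg.news_dup_factor)) if n_news else 0
    head = cfg.head_terms
    titles: list[tuple[str, str]] = []
    for k in range(n_titles):
        term = head[k % len(head)]
        template = _NEWS_TEMPLATES[k % len(_NEWS_TEMPLATES)]
        place = _PLACES[int(rng_text.integers(len(_PLACES)))]
        titles.append((template.format(term=term, place=place, k=k), term))

    tail_terms = [t for t, _w in cfg.tail_terms]
    tail_w = np.array([w for _t, w in cfg.tail_terms], dtype=float)
    tail_p = tail_w / tail_w.sum()

    t0 = datetime(2016, 10, 26, 0, 0, 0)
    tweets: list[Tweet] = []
    records: dict[str, TruthRecord] = {}
    news_seen = 0
    for i in range(n):
        cls = str(classes[i])
        term: str | None = None
        if cls == CLASS_NEWS:
            text, term = titles[news_seen % n_titles]
            news_seen += 1
        elif cls == CLASS_PERSONAL:
            term = tail_terms[int(rng_text.choice(len(tail_terms), p=tail_p))]
            template = _PERSONAL_TEMPLATES[int(rng_text.integers(len(_PERSONAL_TEMPLATES)))]
            text = template.format(
                term=term, handle=_HANDLES[int(rng_text.integers(len(_HANDLES)))]
            )
        elif cls == CLASS_NOISE:
            if rng_text.random() < 0.5:
                template = _JOB_TEMPLATES[int(rng_text.integers(len(_JOB_TEMPLATES)))]
            else:
                template = _CHECKIN_TEMPLATES[int(rng_text.integers(len(_CHECKIN_TEMPLATES)))]
            text = template.format(
                place=_PLACES[int(rng_text.integers(len(_PLACES)))],
                venue=_VENUES[int(rng_text.integers(len(_VENUES)))],
            )
        else:
            template = _BACKGROUND_TEMPLATES[int(rng_text.integers(len(_BACKGROUND_TEMPLATES)))]
            text = template.format(place=_PLACES[int(rng_text.integers(len(_PLACES)))])
        lat, lon, collection = _sample_location(cfg, rng_geo, airports, hospitals)
        tweet_id = f"t{i:07d}"
        tweets.append(
            Tweet(
                tweet_id=tweet_id,
                text=text,
                lat=lat,
                lon=lon,
                timestamp=t0 + timedelta(seconds=97 * i),
                lang=cfg.lang,
            )
        )
        records[tweet_id] = TruthRecord(tweet_id, cls, term, collection)
    return tweets, GroundTruth(records)


def write_terminology_csv(
    catalog: Iterable[tuple[str, float]],
    path: str | Path,
    root_name: str = "disease and disorder classification root",
) -> str:
    """Write the catalog as a flat terminology file (root -> one node per term).

    Returns the root node id, for feeding the lexicon builder.  The default
    root name exceeds the three-content-word limit on purpose, so the class
    label itself never enters the lexicon.
    """
    terms = [t for t, _w in catalog]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id,name,synonyms,children\n")
        children = ",".join(f"d{i}" for i in range(len(terms)))
        fh.write(f'root,{root_name},,"{children}"\n')
        for i, term in enumerate(terms):
            fh.write(f"d{i},{term},,\n")
    return "root"


# -- pipeline scoring ---------------------------------------------------------


@dataclass
class RecoveryMetrics:
    """How well the pipeline recovered what the generator planted."""

    mention_recall: float
    mention_precision: float
    noise_recall: float
    frac_news_hat: float
    frac_noise_hat: float
    confusion: pd.DataFrame  # planted collection x predicted label
    term_counts_match: bool
    n_tweets: int


def evaluate_pipeline(
    tweets: Sequence[Tweet],
    truth: GroundTruth,
    mentions_by_tweet: Mapping[str, Sequence],
    memberships: Sequence[CollectionMembership],
    filter_result,
    news_dup_threshold: int = 5,
) -> RecoveryMetrics:
    """Score pipeline outputs against the ground truth.

    ``frac_news_hat`` counts tweets whose exact text occurs at least
    ``news_dup_threshold`` times in the noise-filtered corpus — the
    duplicate-text heuristic for news titles.  The confusion matrix is
    over the mention-bearing tweets the pipeline geofenced.
    """
    ids_in_corpus = {t.tweet_id for t in tweets}
    missing = set(truth.records) ^ ids_in_corpus
    if missing:
        raise ValidationError(f"truth/corpus id mismatch ({len(missing)} ids)")

    planted = {
        r.tweet_id: r for r in truth.records.values()
        if r.term is not None and r.cls in (CLASS_NEWS, CLASS_PERSONAL)
    }
    n_recalled = sum(
        1
        for tid, r in planted.items()
        if any(m.canonical == r.term for m in mentions_by_tweet.get(tid, ()))
    )
    mention_recall = n_recalled / len(planted) if planted else 1.0

    n_found = sum(len(ms) for ms in mentions_by_tweet.values())
    n_correct = sum(
        1
        for tid, ms in mentions_by_tweet.items()
        for m in ms
        if tid in planted and planted[tid].term == m.canonical
    )
    mention_precision = n_correct / n_found if n_found else 1.0

    noise_ids = {r.tweet_id for r in truth.records.values() if r.cls == CLASS_NOISE}
    flagged = {t.tweet_id for t in filter_result.noise_job} | {
        t.tweet_id for t in filter_result.noise_checkin
    }
    noise_recall = len(noise_ids & flagged) / len(noise_ids) if noise_ids else 1.0
    frac_noise_hat = len(flagged) / len(tweets) if tweets else 0.0

    # news heuristic: a mention-bearing tweet whose exact text recurs
    kept_ids = {t.tweet_id for t in filter_result.kept}
    mention_texts = [
        t.text for t in filter_result.kept if t.tweet_id in mentions_by_tweet
    ]
    text_counts: dict[str, int] = {}
    for text in mention_texts:
        text_counts[text] = text_counts.get(text, 0) + 1
    n_dup = sum(1 for text in mention_texts if text_counts[text] >= news_dup_threshold)
    frac_news_hat = n_dup / len(tweets) if tweets else 0.0

    labels = ["airport", "hospital", "geolocated", "both"]
    confusion = pd.DataFrame(
        0, index=["airport", "hospital", "geolocated"], columns=labels
    )
    for mb in memberships:
        r = truth.records[mb.tweet_id]
        confusion.loc[r.collection, mb.collection_label] += 1

    truth_counts: dict[str, int] = {}
    for tid, r in planted.items():
        if tid in kept_ids:
            truth_counts[r.term] = truth_counts.get(r.term, 0) + 1
    found_counts: dict[str, int] = {}
    for tid, ms in mentions_by_tweet.items():
        for canonical in {m.canonical for m in ms}:
            found_counts[canonical] = found_counts.get(canonical, 0) + 1
    term_counts_match = truth_counts == found_counts

    return RecoveryMetrics(
        mention_recall=mention_recall,
        mention_precision=mention_precision,
        noise_recall=noise_recall,
        frac_news_hat=frac_news_hat,
        frac_noise_hat=frac_noise_hat,
        confusion=confusion,
        term_counts_match=term_counts_match,
        n_tweets=len(tweets),
    )
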