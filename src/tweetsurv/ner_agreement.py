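"""Concept identification interface and dictionary/identifier agreement.

A concept identifier (e.g. a UMLS-backed tool such as MetaMap) maps tweet
text to concepts with a relevance score in (0, 1000], 1000 being most
relevant.  Running such a tool is the user's concern: this module defines
the contract, ships a lexicon-backed stand-in identifier, parses
MMI-style pipe-delimited output files, and computes the two statistics of
interest — the *agreement* between identifier concepts and dictionary
mentions, and per-collection mean relevance scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .corpus_io import Tweet
from .errors import ContractViolation
from .geofence import CollectionMembership
from .lexicon import DiseaseLexicon, normalize_surface
from .matcher import Mention, find_mentions

MAX_SCORE = 1000.0

#: An identifier maps text to (concept, score) pairs.
Identifier = Callable[[str], Sequence[tuple[str, float]]]


@dataclass(frozen=True)
class ConceptHit:
    """One identified concept in one tweet."""

    tweet_id: str
    concept: str
    score: float

    def __post_init__(self) -> None:
        if not self.concept:
            raise ContractViolation("empty concept string")
        if not 0.0 < self.score <= MAX_SCORE:
            raise ContractViolation(f"score {self.score} outside (0, {MAX_SCORE}]")


@dataclass
class LexiconIdentifier:
    """Stand-in identifier backed by the disease lexicon.

    Emits each distinct canonical term matched in the text with the
    maximum relevance score.  Useful for end-to-end runs without an
    external concept-identification service, and as a self-consistency
    reference: on text whose mentions are exact canonical forms its
    agreement with the dictionary matcher is 1 by construction.
    """

    lexicon: DiseaseLexicon
    score: float = MAX_SCORE

    def __call__(self, text: str) -> list[tuple[str, float]]:
        probe = Tweet(
            tweet_id="_probe", text=text, lat=0.0, lon=0.0,
            timestamp=datetime(2000, 1, 1),
        )
        seen: list[str] = []
        for m in find_mentions(probe, self.lexicon):
            if m.canonical not in seen:
                seen.append(m.canonical)
        return [(c, self.score) for c in seen]


def identify_concepts(tweet: Tweet, identifier: Identifier) -> list[ConceptHit]:
    """Run the identifier on one tweet, validating its output contract."""
    hits = []
    for concept, score in identifier(tweet.text):
        hits.append(ConceptHit(tweet_id=tweet.tweet_id, concept=concept, score=float(score)))
    return hits


def identify_corpus(
    tweets: Iterable[Tweet], identifier: Identifier
) -> dict[str, list[ConceptHit]]:
    """Hits per tweet id; tweets without hits are omitted."""
    out: dict[str, list[ConceptHit]] = {}
    for tweet in tweets:
        hits = identify_concepts(tweet, identifier)
        if hits:
            out[tweet.tweet_id] = hits
    return out


def parse_mmi(path: str | Path) -> dict[str, list[ConceptHit]]:
    """Parse pipe-delimited concept-hit lines ``tweet_id|score|concept``."""
    out: dict[str, list[ConceptHit]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            tweet_id, score, concept = line.split("|", 2)
            out.setdefault(tweet_id, []).append(
                ConceptHit(tweet_id=tweet_id, concept=concept, score=float(score))
            )
    return out


@dataclass
class AgreementReport:
    """Identifier/dictionary agreement over a tweet universe.

    ``agreement`` is n_matching / n_with_hits at full precision;
    ``agreement_reported`` rounds to 2 decimals.  When no tweet has hits
    the ratio is undefined and reported as 0 with ``degenerate`` set.
    """

    n_with_hits: int
    n_matching: int
    agreement: float
    mean_score: float
    degenerate: bool = False

    @property
    def agreement_reported(self) -> float:
        return round(self.agreement, 2)


def agreement_score(
    hits_by_tweet: Mapping[str, Sequence[ConceptHit]],
    mentions_by_tweet: Mapping[str, Sequence[Mention]],
) -> AgreementReport:
    """Fraction of hit-bearing tweets whose concepts confirm a mention.

    A tweet matches when any identified concept, normalized the same way
    as lexicon surface forms, equals any of its mention canonicals.
    ``mean_score`` averages the per-tweet best (maximum) score over
    hit-bearing tweets.
    """
    n_with_hits = 0
    n_matching = 0
    best_scores: list[float] = []
    for tweet_id, hits in hits_by_tweet.items():
        if not hits:
            continue
        n_with_hits += 1
        best_scores.append(max(h.score for h in hits))
        canonicals = {m.canonical for m in mentions_by_tweet.get(tweet_id, ())}
        if any(normalize_surface(h.concept) in canonicals for h in hits):
            n_matching += 1
    if n_with_hits == 0:
        return AgreementReport(0, 0, 0.0, 0.0, degenerate=True)
    return AgreementReport(
        n_with_hits=n_with_hits,
        n_matching=n_matching,
        agreement=n_matching / n_with_hits,
        mean_score=sum(best_scores) / len(best_scores),
    )


def mean_relevance(
    hits_by_tweet: Mapping[str, Sequence[ConceptHit]],
    memberships: Iterable[CollectionMembership],
    over_all_tweets: bool = False,
) -> dict[str, float]:
    """Mean per-tweet best score for each collection.

    Per tweet, relevance is the maximum hit score.  By default the mean is
    taken over hit-bearing tweets only; with ``over_all_tweets`` every
    collection member enters the denominator (hitless tweets as 0) — both
    bases are plausible readings of an "average relevance score" and are
    reported separately.  Collections without any hit-bearing member are
    absent from the result.
    """
    sums: dict[str, float] = {}
    n_hit: dict[str, int] = {}
    n_all: dict[str, int] = {}
    for mb in memberships:
        labels = []
        if mb.in_airport:
            labels.append("airport")
        if mb.in_hospital:
            labels.append("hospital")
        if not labels:
            labels.append("geolocated")
        hits = hits_by_tweet.get(mb.tweet_id, ())
        best = max((h.score for h in hits), default=None)
        for label in labels:
            n_all[label] = n_all.get(label, 0) + 1
            if best is not None:
                sums[label] = sums.get(label, 0.0) + best
                n_hit[label] = n_hit.get(label, 0) + 1
    denom = n_all if over_all_tweets else n_hit
    return {
        label: sums[label] / denom[label]
        for label in sums
        if denom.get(label)
    }
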