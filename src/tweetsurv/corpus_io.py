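"""Corpus reading/writing and regular-expression noise filtering.

The corpus dialect is JSON Lines: one message object per line with fields
``id, text, lat, lon, created_at, lang`` (ISO-8601 timestamps).  Two noise
families are removed before any analysis: job advertisements and templated
location-sharing ("check-in") messages.  The shipped default patterns
reproduce the structure of the canonical examples of both families and are
user-overridable through the YAML config.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import CorpusFormatError, ValidationError

logger = logging.getLogger(__name__)

NOISE_JOB = "job"
NOISE_CHECKIN = "checkin"

DEFAULT_JOB_PATTERNS = (
    r"#hiring\b",
    r"#job\b",
    r"\bjob opening\b",
    r"\bwe(?:'|’)?re hiring\b",
)
DEFAULT_CHECKIN_PATTERNS = (
    r"^i(?:'|’)?m at .+ in ",
    r"^just checked in (?:at|to)\b",
)


@dataclass(frozen=True)
class Tweet:
    """One geolocated message."""

    tweet_id: str
    text: str
    lat: float
    lon: float
    timestamp: datetime
    lang: str = "en"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValidationError("tweet text is empty")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude out of bounds: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"longitude out of bounds: {self.lon}")


@dataclass
class ReadReport:
    """Per-read accounting of accepted and rejected lines."""

    n_read: int = 0
    n_malformed: int = 0
    n_lang_dropped: int = 0


def _parse_line(line: str, lang: str | None) -> Tweet | None:
    obj = json.loads(line)
    tweet = Tweet(
        tweet_id=str(obj["id"]),
        text=obj["text"],
        lat=float(obj["lat"]),
        lon=float(obj["lon"]),
        timestamp=datetime.fromisoformat(obj["created_at"]),
        lang=obj.get("lang", "und"),
    )
    if lang is not None and tweet.lang != lang:
        return None
    return tweet


def read_corpus(path: str | Path, lang: str | None = "en") -> tuple[list[Tweet], ReadReport]:
    """Read a JSONL corpus, validating each record.

    Malformed lines (bad JSON, missing fields, out-of-bounds coordinates)
    are counted and skipped; messages in other languages are dropped, as the
    analysis is monolingual.  If more than half of the non-empty lines are
    malformed the file is rejected with :class:`CorpusFormatError`.
    """
    report = ReadReport()
    tweets: list[Tweet] = []
    seen: set[str] = set()
    n_lines = 0
    try:
        fh = open(path, encoding="utf-8")
    except OSError as exc:
        raise CorpusFormatError(f"cannot read corpus {path}: {exc}") from exc
    with fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            n_lines += 1
            try:
                tweet = _parse_line(line, lang)
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                report.n_malformed += 1
                logger.debug("skipping malformed line: %s", exc)
                continue
            if tweet is None:
                report.n_lang_dropped += 1
                continue
            if tweet.tweet_id in seen:
                report.n_malformed += 1
                logger.debug("skipping duplicate tweet id %s", tweet.tweet_id)
                continue
            seen.add(tweet.tweet_id)
            tweets.append(tweet)
            report.n_read += 1
    if n_lines and report.n_malformed > n_lines / 2:
        raise CorpusFormatError(
            f"{report.n_malformed}/{n_lines} lines malformed — not a corpus file?"
        )
    return tweets, report


def iter_corpus(path: str | Path, lang: str | None = "en") -> Iterator[Tweet]:
    """Streaming variant of :func:`read_corpus` (no malformed-rate guard)."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                tweet = _parse_line(line, lang)
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                continue
            if tweet is not None:
                yield tweet


def write_corpus(tweets: Iterable[Tweet], path: str | Path) -> int:
    """Write tweets as JSONL; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(
                json.dumps(
                    {
                        "id": t.tweet_id,
                        "text": t.text,
                        "lat": t.lat,
                        "lon": t.lon,
                        "created_at": t.timestamp.isoformat(),
                        "lang": t.lang,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            n += 1
    return n


@dataclass
class NoiseRuleSet:
    """Compiled noise patterns, one family for job ads, one for check-ins."""

    job_patterns: list[re.Pattern] = field(default_factory=list)
    checkin_patterns: list[re.Pattern] = field(default_factory=list)

    @classmethod
    def compile(
        cls,
        job_patterns: Sequence[str] = DEFAULT_JOB_PATTERNS,
        checkin_patterns: Sequence[str] = DEFAULT_CHECKIN_PATTERNS,
    ) -> "NoiseRuleSet":
        if not job_patterns or not checkin_patterns:
            raise ValidationError("each noise family needs at least one pattern")
        return cls(
            job_patterns=[re.compile(p, re.IGNORECASE) for p in job_patterns],
            checkin_patterns=[re.compile(p, re.IGNORECASE) for p in checkin_patterns],
        )

    @classmethod
    def default(cls) -> "NoiseRuleSet":
        return cls.compile()


def is_noise(tweet: Tweet, rules: NoiseRuleSet) -> tuple[bool, str | None]:
    """Whether the tweet matches a noise family; job takes precedence."""
    for pat in rules.job_patterns:
        if pat.search(tweet.text):
            return True, NOISE_JOB
    for pat in rules.checkin_patterns:
        if pat.search(tweet.text):
            return True, NOISE_CHECKIN
    return False, None


@dataclass
class FilterResult:
    """Partition of a corpus into kept messages and the two noise families."""

    kept: list[Tweet]
    noise_job: list[Tweet]
    noise_checkin: list[Tweet]

    @property
    def n_total(self) -> int:
        return len(self.kept) + len(self.noise_job) + len(self.noise_checkin)


def filter_corpus(tweets: Iterable[Tweet], rules: NoiseRuleSet | None = None) -> FilterResult:
    """Split a corpus into kept vs. noise tweets (idempotent on ``kept``)."""
    if rules is None:
        rules = NoiseRuleSet.default()
    result = FilterResult([], [], [])
    for tweet in tweets:
        noisy, family = is_noise(tweet, rules)
        if not noisy:
            result.kept.append(tweet)
        elif family == NOISE_JOB:
            result.noise_job.append(tweet)
        else:
            result.noise_checkin.append(tweet)
    return result
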