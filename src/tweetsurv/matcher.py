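"""Strict dictionary matching of disease terms in tweet text.

A mention is a case-insensitive, whole-token-sequence occurrence of a
lexicon surface form: word boundaries are required on both ends and the
tokens of a multi-word term may be separated by any run of non-word
characters ("kidney stone", "kidney-stone" and "kidney  stone" all match
the term "kidney stone", but "kidneystone" does not).  Terms are strict —
"muscle soreness and atrophy" does not match "muscle atrophy".

Candidate occurrences are gathered in two passes (canonical names first,
then synonyms) and overlaps are resolved longest-first, then leftmost, so
each character position contributes to at most one mention.  Hashtag
bodies are searchable: "#flu" matches a single-word term because "#" is a
non-word character.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import Tweet
from .lexicon import DiseaseLexicon

# Word characters are letters and digits; underscore is a boundary so that
# handle fragments like "flu_fan" do not hide or fabricate matches.
_W = r"[^\W_]"
_NW = r"[\W_]"


@dataclass(frozen=True)
class Mention:
    """A matched disease term with its span (0-based, half-open)."""

    tweet_id: str
    surface: str
    canonical: str
    start: int
    end: int
    via_synonym: bool


@lru_cache(maxsize=65536)
def _surface_pattern(surface: str) -> re.Pattern:
    tokens = [re.escape(t) for t in surface.split()]
    body = f"{_NW}+".join(tokens)
    return re.compile(rf"(?<!{_W}){body}(?!{_W})", re.IGNORECASE | re.UNICODE)


def find_mentions(tweet: Tweet, lexicon: DiseaseLexicon) -> list[Mention]:
    """All non-overlapping disease mentions in one tweet.

    Returned in reading order.  Precedence for overlapping candidates:
    canonical-name pass before synonym pass, then longer match, then
    leftmost start.
    """
    text = tweet.text
    text_lower = text.lower()
    candidates: list[tuple[int, int, int, int, str, str]] = []
    for surface, canonical in lexicon.surface_map.items():
        first_token = surface.split()[0]
        if first_token not in text_lower:
            continue
        pass_rank = 0 if surface == canonical else 1
        for m in _surface_pattern(surface).finditer(text):
            candidates.append(
                (pass_rank, -(m.end() - m.start()), m.start(), m.end(), surface, canonical)
            )
    candidates.sort()
    chosen: list[tuple[int, int, str, str, bool]] = []
    taken: list[tuple[int, int]] = []
    for pass_rank, _neglen, start, end, surface, canonical in candidates:
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        chosen.append((start, end, surface, canonical, pass_rank == 1))
    chosen.sort()
    return [
        Mention(
            tweet_id=tweet.tweet_id,
            surface=text[start:end],
            canonical=canonical,
            start=start,
            end=end,
            via_synonym=via_synonym,
        )
        for start, end, _surface, canonical, via_synonym in chosen
    ]


def find_corpus_mentions(
    tweets: Iterable[Tweet], lexicon: DiseaseLexicon
) -> dict[str, list[Mention]]:
    """Mentions per tweet id, omitting tweets without any mention."""
    out: dict[str, list[Mention]] = {}
    for tweet in tweets:
        mentions = find_mentions(tweet, lexicon)
        if mentions:
            out[tweet.tweet_id] = mentions
    return out


def write_mentions(mentions_by_tweet: Mapping[str, Sequence[Mention]], path: str | Path) -> None:
    """TSV export: ``tweet_id, canonical, surface, start, end, via_synonym``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tweet_id\tcanonical\tsurface\tstart\tend\tvia_synonym\n")
        for tweet_id in mentions_by_tweet:
            for m in mentions_by_tweet[tweet_id]:
                fh.write(
                    f"{m.tweet_id}\t{m.canonical}\t{m.surface}\t{m.start}\t{m.end}"
                    f"\t{int(m.via_synonym)}\n"
                )
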