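"""Tweet normalization, POS tagging, and context patterns around DISEASE.

Before tagging, five substitutions are applied in order: (1) the matched
disease term (if any) becomes the placeholder ``DISEASE``; (2) usernames
(words immediately preceded by ``@``) become ``@username``; (3) URLs become
``URL``; (4) a free-standing ``@`` (no word character on either side)
becomes ``at``; (5) remaining punctuation is removed.  The text is then
whitespace-tokenized and each token receives a Penn-Treebank-style tag
from a pluggable tagger.

A *context pattern* is the tag sequence of a contiguous window around the
DISEASE token, characterized by its shape ``(l, r)`` — l tags on the left,
r on the right.  A tweet with L tags left of the placeholder and R right
of it yields every shape with ``0 <= l <= L``, ``0 <= r <= R``,
``|l - r| <= 1`` and ``l + r >= 1``: windows grow symmetrically and stop
one step after a side is exhausted, so a (2,1)-context yields the four
patterns of shapes (0,1), (1,0), (1,1), (2,1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ContractViolation, StaleMentionError, ValidationError
from .matcher import Mention

DISEASE_TOKEN = "DISEASE"
USERNAME_TOKEN = "@username"
URL_TOKEN = "URL"

_USERNAME_RE = re.compile(r"@[A-Za-z0-9_]+")
_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_LONE_AT_RE = re.compile(r"(?<![0-9A-Za-z_])@(?![0-9A-Za-z_])")
_BARE_MARK_RE = re.compile(r"[@#](?![0-9A-Za-z_])")
_PUNCT_RE = re.compile(r"[^\w\s@#]", re.UNICODE)

#: A tagger maps a token sequence to an equal-length tag sequence.
Tagger = Callable[[Sequence[str]], Sequence[str]]


def normalize_text(text: str, mention: Mention | None = None) -> str:
    """Apply the five normalization steps; output is whitespace-clean.

    Only the given mention (by convention the leftmost) is replaced by the
    placeholder, preserving the single-DISEASE invariant.  Punctuation is
    deleted in place ("I'm" -> "Im"); ``@`` of ``@username`` and ``#`` of
    hashtags survive so those tokens stay searchable.
    """
    if mention is not None:
        if text[mention.start : mention.end].lower() != mention.surface.lower():
            raise StaleMentionError(
                f"mention span [{mention.start}:{mention.end}] does not match text"
            )
        text = text[: mention.start] + DISEASE_TOKEN + text[mention.end :]
    text = _USERNAME_RE.sub(USERNAME_TOKEN, text)
    text = _URL_RE.sub(URL_TOKEN, text)
    text = _LONE_AT_RE.sub("at", text)
    text = _BARE_MARK_RE.sub(" ", text)
    text = _PUNCT_RE.sub("", text)
    return " ".join(text.split())


@dataclass(frozen=True)
class TaggedTweet:
    """Token/tag sequences with the position of the DISEASE placeholder."""

    tokens: tuple[str, ...]
    tags: tuple[str, ...]
    disease_index: int | None = None


def tag(text: str, tagger: Tagger) -> TaggedTweet:
    """Tokenize a normalized text and tag it with the given tagger.

    The tagger must return one tag per token (anything else is a
    :class:`ContractViolation`).  ``DISEASE``, ``@username`` and ``URL``
    pass through as single tokens.
    """
    tokens = tuple(text.split())
    if not tokens:
        return TaggedTweet(tokens=(), tags=(), disease_index=None)
    tags = tuple(tagger(tokens))
    if len(tags) != len(tokens):
        raise ContractViolation(
            f"tagger returned {len(tags)} tags for {len(tokens)} tokens"
        )
    n_disease = tokens.count(DISEASE_TOKEN)
    if n_disease > 1:
        raise ValidationError("normalized text contains more than one DISEASE token")
    disease_index = tokens.index(DISEASE_TOKEN) if n_disease else None
    return TaggedTweet(tokens=tokens, tags=tags, disease_index=disease_index)


@dataclass
class DictTagger:
    """Deterministic lookup tagger for tests and frozen vocabularies."""

    mapping: Mapping[str, str]
    default: str = "NN"

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        return [
            self.mapping.get(t, self.mapping.get(t.lower(), self.default))
            for t in tokens
        ]


_CLOSED_CLASS = {
    "a": "DT", "an": "DT", "the": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT",
    "in": "IN", "of": "IN", "at": "IN", "on": "IN", "for": "IN", "with": "IN",
    "from": "IN", "by": "IN", "about": "IN", "after": "IN", "before": "IN",
    "over": "IN", "under": "IN", "near": "IN",
    "to": "TO",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC", "so": "CC", "yet": "CC",
    "i": "PRP", "you": "PRP", "he": "PRP", "she": "PRP", "it": "PRP",
    "we": "PRP", "they": "PRP", "me": "PRP", "him": "PRP", "her": "PRP",
    "us": "PRP", "them": "PRP",
    "my": "PRP$", "your": "PRP$", "his": "PRP$", "its": "PRP$",
    "our": "PRP$", "their": "PRP$",
    "will": "MD", "would": "MD", "can": "MD", "could": "MD", "may": "MD",
    "might": "MD", "must": "MD", "shall": "MD", "should": "MD",
    "is": "VBZ", "has": "VBZ", "does": "VBZ",
    "am": "VBP", "are": "VBP", "have": "VBP", "do": "VBP",
    "was": "VBD", "were": "VBD", "had": "VBD", "did": "VBD",
    "be": "VB", "been": "VBN", "being": "VBG",
    "not": "RB", "again": "RB", "very": "RB", "now": "RB",
}


class PennRuleTagger:
    """Built-in deterministic tagger over the Penn Treebank inventory.

    Closed-class words are looked up; open-class words are tagged by
    suffix/shape heuristics (``-ly`` RB, ``-ing`` VBG, ``-ed`` VBD, digits
    CD, capitalized NNP, plural NNS, otherwise NN).  Not a trained model —
    its value is determinism: pattern statistics are reproducible across
    runs and machines.  Any conforming tagger can be plugged in instead.
    """

    SPECIAL = {DISEASE_TOKEN: "NN", USERNAME_TOKEN: "NNP", URL_TOKEN: "NN"}

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        return [self._tag_one(t) for t in tokens]

    def _tag_one(self, token: str) -> str:
        if token in self.SPECIAL:
            return self.SPECIAL[token]
        low = token.lower()
        if low in _CLOSED_CLASS:
            return _CLOSED_CLASS[low]
        if low.lstrip("#").isdigit():
            return "CD"
        if token[0].isupper() or token.startswith("#"):
            return "NNP"
        if low.endswith("ly"):
            return "RB"
        if low.endswith("ing"):
            return "VBG"
        if low.endswith("ed"):
            return "VBD"
        if low.endswith("s") and len(low) > 3 and not low.endswith("ss"):
            return "NNS"
        return "NN"


@dataclass(frozen=True)
class POSPattern:
    """A tag window around DISEASE with shape (l, r)."""

    left: tuple[str, ...]
    right: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.left), len(self.right)

    def rendered(self) -> str:
        parts = list(self.left) + [DISEASE_TOKEN] + list(self.right)
        return ",".join(f"'{p}'" for p in parts)


def admissible_shapes(L: int, R: int) -> list[tuple[int, int]]:
    """All window shapes for L left / R right available tags.

    Ordered by total width, then left width: {(l, r): 0 <= l <= L,
    0 <= r <= R, |l - r| <= 1, l + r >= 1}.
    """
    shapes = [
        (l, r)
        for total in range(1, L + R + 1)
        for l in range(total + 1)
        for r in (total - l,)
        if l <= L and r <= R and abs(l - r) <= 1
    ]
    return shapes


def generate_patterns(t: TaggedTweet) -> list[POSPattern]:
    """Enumerate the context patterns of one tagged tweet.

    A tweet without the DISEASE placeholder yields no patterns (not an
    error).  Every pattern's tags are the slices adjacent to the
    placeholder.
    """
    if t.disease_index is None:
        return []
    di = t.disease_index
    L = di
    R = len(t.tags) - di - 1
    return [
        POSPattern(left=t.tags[di - l : di], right=t.tags[di + 1 : di + 1 + r])
        for l, r in admissible_shapes(L, R)
    ]


def pattern_frequencies(
    patterns: Iterable[POSPattern], min_count: int = 1
) -> pd.DataFrame:
    """Aggregate patterns into a ranked frequency table.

    Rows: ``pattern`` (rendered form), ``shape_l``, ``shape_r``, ``count``;
    descending count with lexicographic tie-break; rows below *min_count*
    are omitted.
    """
    counts: dict[tuple[str, int, int], int] = {}
    for p in patterns:
        key = (p.rendered(), *p.shape)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"pattern": k[0], "shape_l": k[1], "shape_r": k[2], "count": c}
        for k, c in counts.items()
        if c >= min_count
    ]
    df = pd.DataFrame(rows, columns=["pattern", "shape_l", "shape_r", "count"])
    if len(df):
        df = df.sort_values(
            ["count", "pattern"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df
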