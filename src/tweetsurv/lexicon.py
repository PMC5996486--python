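"""Disease-term dictionary built from a hierarchical clinical terminology.

The terminology is a forest of nodes (class -> sub-class links, as in the
Disease branch of SNOMED-CT-style vocabularies); each node carries a
canonical name and optional synonyms.  Harvesting a lexicon means collecting
the names and synonyms of every node reachable from a chosen root, then
discarding surface forms that are too long to plausibly appear in short
messages: forms with more than ``max_content_words`` tokens, where
determiners, conjunctions and prepositions ("of", "from", "the", "a",
"and", "to") do not count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import TerminologyError, TerminologyLookupError, ValidationError

logger = logging.getLogger(__name__)

#: Function words excluded from the content-word count.
DEFAULT_STOPWORDS: frozenset[str] = frozenset({"of", "from", "the", "a", "and", "to"})

#: Surface forms with more content words than this are dropped.
DEFAULT_MAX_CONTENT_WORDS = 3


@dataclass(frozen=True)
class TerminologyNode:
    """One class in the terminology hierarchy."""

    node_id: str
    name: str
    synonyms: tuple[str, ...] = ()
    children: tuple[str, ...] = ()


def normalize_surface(surface: str) -> str:
    """Lookup normalization: lowercase and collapse internal whitespace."""
    return " ".join(surface.lower().split())


def content_word_count(term: str, stopwords: Iterable[str] = DEFAULT_STOPWORDS) -> int:
    """Number of whitespace tokens of *term* that are not function words.

    The comparison is case-insensitive.  Hyphenated compounds count as a
    single token.  An empty or blank term is a :class:`ValidationError`.
    """
    tokens = term.split()
    if not tokens:
        raise ValidationError("content_word_count: term is empty")
    stop = {s.lower() for s in stopwords}
    return sum(1 for t in tokens if t.lower() not in stop)


def read_terminology(path: str | Path) -> dict[str, TerminologyNode]:
    """Read a terminology CSV into a node table keyed by node id.

    Expected columns: ``node_id,name,synonyms,children`` with synonyms
    pipe-delimited and child ids comma-delimited.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"node_id", "name", "synonyms", "children"}
    missing = required - set(df.columns)
    if missing:
        raise TerminologyError(f"terminology file missing columns: {sorted(missing)}")
    nodes: dict[str, TerminologyNode] = {}
    for row in df.itertuples(index=False):
        if row.node_id in nodes:
            raise TerminologyError(f"duplicate node_id {row.node_id!r}")
        synonyms = tuple(s.strip() for s in row.synonyms.split("|") if s.strip())
        children = tuple(c.strip() for c in row.children.split(",") if c.strip())
        nodes[row.node_id] = TerminologyNode(row.node_id, row.name, synonyms, children)
    for node in nodes.values():
        for child in node.children:
            if child not in nodes:
                raise TerminologyError(
                    f"node {node.node_id!r} references unknown child {child!r}"
                )
    return nodes


def collect_terms(
    nodes: Mapping[str, TerminologyNode], root: str
) -> list[tuple[str, tuple[str, ...]]]:
    """Collect ``(name, synonyms)`` of *root* and every descendant.

    Each reachable node contributes exactly once, in depth-first preorder.
    An unknown root raises :class:`TerminologyLookupError`; a cycle through
    child links raises :class:`TerminologyError`.
    """
    if root not in nodes:
        raise TerminologyLookupError(root)
    collected: list[tuple[str, tuple[str, ...]]] = []
    visited: set[str] = set()
    on_path: set[str] = set()

    def visit(node_id: str) -> None:
        if node_id in on_path:
            raise TerminologyError(f"cycle detected at node {node_id!r}")
        if node_id in visited:
            return
        visited.add(node_id)
        on_path.add(node_id)
        node = nodes[node_id]
        collected.append((node.name, node.synonyms))
        for child in node.children:
            if child not in nodes:
                raise TerminologyLookupError(child)
            visit(child)
        on_path.discard(node_id)

    visit(root)
    return collected


@dataclass
class DiseaseLexicon:
    """Normalized disease dictionary: surface form -> canonical term.

    ``surface_map`` keys are normalized surface forms (canonical names and
    synonyms); every canonical term maps to itself.  All retained surface
    forms satisfy the content-word bound.
    """

    canonical_terms: set[str]
    surface_map: dict[str, str]
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    max_content_words: int = DEFAULT_MAX_CONTENT_WORDS
    _max_tokens: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        self._max_tokens = max((len(s.split()) for s in self.surface_map), default=0)

    def __len__(self) -> int:
        return len(self.surface_map)

    def __contains__(self, surface: str) -> bool:
        return normalize_surface(surface) in self.surface_map

    @property
    def max_surface_tokens(self) -> int:
        """Token length of the longest surface form (for window searches)."""
        return self._max_tokens

    def lookup(self, surface: str) -> str | None:
        """Canonical term for a surface form, or None."""
        return self.surface_map.get(normalize_surface(surface))

    def entries(self) -> list[tuple[str, tuple[str, ...]]]:
        """Rebuild the ``(canonical, synonyms)`` view of the lexicon."""
        syns: dict[str, list[str]] = {c: [] for c in sorted(self.canonical_terms)}
        for surface, canonical in self.surface_map.items():
            if surface != canonical:
                syns[canonical].append(surface)
        return [(c, tuple(sorted(s))) for c, s in syns.items()]


def build_lexicon(
    terms: Iterable[tuple[str, Sequence[str]]],
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    max_content_words: int = DEFAULT_MAX_CONTENT_WORDS,
) -> DiseaseLexicon:
    """Filter and normalize harvested terms into a :class:`DiseaseLexicon`.

    A record whose canonical name exceeds the content-word bound is dropped
    entirely, synonyms included; an over-long synonym of a retained name is
    dropped individually.  A synonym colliding with a different canonical
    term keeps the mapping encountered first (a warning is logged) — the
    terminology contains polysemous layman forms and no disambiguation is
    attempted at lexicon level.
    """
    stop = frozenset(s.lower() for s in stopwords)
    canonical_terms: set[str] = set()
    surface_map: dict[str, str] = {}
    for name, synonyms in terms:
        canonical = normalize_surface(name)
        if not canonical:
            continue
        if content_word_count(canonical, stop) > max_content_words:
            logger.debug("dropping long term %r (with %d synonyms)", name, len(synonyms))
            continue
        if canonical in surface_map and surface_map[canonical] != canonical:
            logger.warning(
                "canonical name %r already mapped to %r; keeping first mapping",
                canonical,
                surface_map[canonical],
            )
            continue
        canonical_terms.add(canonical)
        surface_map[canonical] = canonical
        for syn in synonyms:
            surface = normalize_surface(syn)
            if not surface or content_word_count(surface, stop) > max_content_words:
                continue
            existing = surface_map.get(surface)
            if existing is not None and existing != canonical:
                logger.warning(
                    "synonym %r of %r collides with %r; keeping first mapping",
                    surface,
                    canonical,
                    existing,
                )
                continue
            surface_map[surface] = canonical
    return DiseaseLexicon(
        canonical_terms=canonical_terms,
        surface_map=surface_map,
        stopwords=stop,
        max_content_words=max_content_words,
    )


def lexicon_from_terminology(
    path: str | Path,
    root: str,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    max_content_words: int = DEFAULT_MAX_CONTENT_WORDS,
) -> DiseaseLexicon:
    """Convenience: read a terminology file and build the lexicon from *root*."""
    nodes = read_terminology(path)
    return build_lexicon(collect_terms(nodes, root), stopwords, max_content_words)


def write_lexicon(lexicon: DiseaseLexicon, path: str | Path) -> None:
    """Serialize as TSV ``surface_form<TAB>canonical_term`` (sorted)."""
    with open(path, "w", encoding="utf-8") as fh:
        for surface in sorted(lexicon.surface_map):
            fh.write(f"{surface}\t{lexicon.surface_map[surface]}\n")


def read_lexicon(path: str | Path) -> DiseaseLexicon:
    """Read a TSV lexicon written by :func:`write_lexicon`."""
    surface_map: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            surface, canonical = line.split("\t")
            surface_map[surface] = canonical
    canonical_terms = set(surface_map.values())
    return DiseaseLexicon(canonical_terms=canonical_terms, surface_map=surface_map)
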