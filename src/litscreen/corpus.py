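"""Corpus construction for guideline-oriented literature screening.

Builds a labelled binary-classification dataset from raw bibliographic
records: fuzzy key-phrase screening of titles/abstracts, deduplication,
removal of records without resolvable journal metadata, positive/negative
labelling against a citation list, and majority-class downsampling.

The fuzzy matching rule: a key phrase (an ordered list of words) matches a
text when its words occur in order with at most ``max_gap`` other words
between each consecutive pair.  The canonical example is the phrase
("cervical", "pain") matching the title "... interventions for cervical
spine joint pain ..." with two intervening words.
"""

from __future__ import annotations

import unicodedata
import warnings
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "KeyPhrase",
    "RawRecord",
    "Article",
    "MatchResult",
    "DEFAULT_PHRASES",
    "normalize_tokens",
    "phrase_match",
    "screen_record",
    "deduplicate",
    "filter_journal_info",
    "assign_labels",
    "downsample_negatives",
    "word_frequencies",
]


@dataclass(frozen=True)
class KeyPhrase:
    """An ordered multi-word search phrase with a proximity window.

    Parameters
    ----------
    words
        Lowercase words that must occur in this order.
    max_gap
        Maximum number of other tokens allowed between each consecutive
        pair of phrase words (default 3).
    """

    words: tuple[str, ...]
    max_gap: int = 3

    def __post_init__(self) -> None:
        if len(self.words) < 2:
            raise ValueError("a key phrase needs at least two words")
        for w in self.words:
            if not w or any(c.isspace() for c in w):
                raise ValueError(f"phrase words must be non-empty and whitespace-free: {w!r}")
        if self.max_gap < 0:
            raise ValueError("max_gap must be non-negative")

    @classmethod
    def from_string(cls, text: str, max_gap: int = 3) -> "KeyPhrase":
        return cls(tuple(text.lower().split()), max_gap=max_gap)


#: The default screening phrases for the neck-pain corpus.  Order-sensitive:
#: "neck pain" and "pain neck" are distinct entries.
DEFAULT_PHRASES: tuple[KeyPhrase, ...] = tuple(
    KeyPhrase.from_string(p)
    for p in ("back pain", "pain back", "neck pain", "pain neck", "cervical pain")
)


@dataclass(frozen=True)
class RawRecord:
    """One bibliographic record before labelling."""

    id: str
    title: str
    abstract: str = ""
    journal_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.title:
            raise ValueError(f"record {self.id!r}: title must be non-empty")


@dataclass(frozen=True)
class Article:
    """A labelled record; ``label`` is 1 for guideline-cited (positive) articles."""

    id: str
    title: str
    abstract: str
    journal_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"article {self.id!r}: label must be 0 or 1")
        if not self.journal_id:
            raise ValueError(f"article {self.id!r}: journal_id required")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one phrase against one token list.

    ``gap`` counts the tokens strictly between matched phrase words at the
    leftmost match (summed over consecutive pairs for phrases longer than
    two words); ``positions`` are the matched token indices.
    """

    matched: bool
    gap: Optional[int] = None
    positions: tuple[int, ...] = ()


@lru_cache(maxsize=4096)
def _fold_char(c: str) -> str:
    return " " if unicodedata.category(c).startswith("P") else c


def normalize_tokens(text: str) -> list[str]:
    """Lowercase ``text``, replace Unicode punctuation (incl. hyphens) with
    spaces, and split on whitespace.  Total and deterministic."""
    lowered = text.lower()
    return "".join(_fold_char(c) for c in lowered).split()


def phrase_match(tokens: Sequence[str], phrase: KeyPhrase) -> MatchResult:
    """Match ``phrase`` against an already-normalized token list.

    Returns the leftmost (lexicographically smallest by index tuple) match
    satisfying the gap constraint between every consecutive word pair.
    Backtracking search: the earliest occurrence of a word is not always on
    a feasible match, so greedy scanning is insufficient.
    """
    words = phrase.words
    g = phrase.max_gap
    occurrences = [[i for i, t in enumerate(tokens) if t == w] for w in words]
    if any(not occ for occ in occurrences):
        return MatchResult(False)

    def extend(prefix: list[int], widx: int) -> Optional[list[int]]:
        if widx == len(words):
            return prefix
        last = prefix[-1]
        for j in occurrences[widx]:
            if j <= last:
                continue
            if j - last - 1 > g:
                break  # occurrences ascend, later ones only widen the gap
            hit = extend(prefix + [j], widx + 1)
            if hit is not None:
                return hit
        return None

    for start in occurrences[0]:
        hit = extend([start], 1)
        if hit is not None:
            gap = hit[-1] - hit[0] - (len(hit) - 1)
            return MatchResult(True, gap=gap, positions=tuple(hit))
    return MatchResult(False)


def screen_record(record: RawRecord, phrases: Iterable[KeyPhrase] = DEFAULT_PHRASES) -> bool:
    """True iff any phrase matches the record's title or abstract."""
    fields = [normalize_tokens(record.title)]
    if record.abstract:
        fields.append(normalize_tokens(record.abstract))
    return any(phrase_match(toks, p).matched for p in phrases for toks in fields)


def deduplicate(records: Sequence[RawRecord]) -> list[RawRecord]:
    """Drop duplicates, keeping the first occurrence (stable order).

    Two records are duplicates when they share an id, or failing that, an
    identical normalized title.
    """
    seen_ids: set[str] = set()
    seen_titles: set[tuple[str, ...]] = set()
    kept: list[RawRecord] = []
    for rec in records:
        title_key = tuple(normalize_tokens(rec.title))
        if rec.id in seen_ids or title_key in seen_titles:
            continue
        seen_ids.add(rec.id)
        seen_titles.add(title_key)
        kept.append(rec)
    return kept


def filter_journal_info(
    records: Sequence[RawRecord], journal_table: Mapping[str, object]
) -> list[RawRecord]:
    """Keep exactly the records whose journal_id resolves in ``journal_table``."""
    return [r for r in records if r.journal_id is not None and r.journal_id in journal_table]


def assign_labels(records: Sequence[RawRecord], positive_ids: set[str]) -> list[Article]:
    """Label records: 1 if cited by guidelines/systematic reviews, else 0.

    Positive ids that do not appear among the records trigger a warning but
    no failure (they may have been dropped by earlier filters).
    """
    record_ids = {r.id for r in records}
    unknown = positive_ids - record_ids
    if unknown:
        warnings.warn(
            f"{len(unknown)} positive id(s) not present among the records "
            f"(e.g. {sorted(unknown)[:3]})",
            stacklevel=2,
        )
    return [
        Article(
            id=r.id,
            title=r.title,
            abstract=r.abstract,
            journal_id=r.journal_id,  # type: ignore[arg-type]
            label=1 if r.id in positive_ids else 0,
        )
        for r in records
    ]


def downsample_negatives(
    articles: Sequence[Article], target_pos_frac: float = 0.3, seed: int = 0
) -> list[Article]:
    """Uniformly subsample negatives, without replacement, so positives make
    up ``target_pos_frac`` of the result (all positives are retained).

    The draw size is round(n_pos * (1 - f) / f); with 1,005 positives and
    f = 0.3 this is exactly 2,345.  Output preserves input order.
    """
    if not 0.0 < target_pos_frac < 1.0:
        raise ValueError("target_pos_frac must lie in (0, 1)")
    positives = [a for a in articles if a.label == 1]
    negatives = [a for a in articles if a.label == 0]
    if not positives:
        raise ValueError("downsampling requires at least one positive article")
    n_draw = int(np.floor(len(positives) * (1.0 - target_pos_frac) / target_pos_frac + 0.5))
    if n_draw > len(negatives):
        raise ValueError(
            f"cannot draw {n_draw} negatives without replacement: only "
            f"{len(negatives)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(negatives), size=n_draw, replace=False).tolist())
    keep_ids = {positives[i].id for i in range(len(positives))}
    keep_ids |= {negatives[i].id for i in chosen}
    return [a for a in articles if a.id in keep_ids]


def word_frequencies(articles: Sequence[Article], k: int = 100) -> list[tuple[str, int]]:
    """Top-``k`` normalized-token frequencies over titles and abstracts,
    descending by count with lexicographic tie-break."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for a in articles:
        counts.update(normalize_tokens(a.title))
        counts.update(normalize_tokens(a.abstract))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
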