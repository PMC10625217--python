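"""Corpus construction: tokenization, fuzzy phrase matching, dedup,
labelling, downsampling."""

import itertools
import unicodedata

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from litscreen.corpus import (
    Article,
    DEFAULT_PHRASES,
    KeyPhrase,
    RawRecord,
    assign_labels,
    deduplicate,
    downsample_negatives,
    filter_journal_info,
    normalize_tokens,
    phrase_match,
    screen_record,
    word_frequencies,
)

GUIDELINE_TITLE = (
    "Consensus practice guidelines on interventions for cervical spine "
    "joint pain from a multispecialty international working group"
)


# --- independent oracles ---------------------------------------------------


def _tokens_oracle(text: str) -> list[str]:
    """Regex-free character walk: accumulate non-punctuation characters of
    the lowercased text, flushing words at whitespace/punctuation."""
    words, current = [], []
    for c in text.lower():
        if c.isspace() or unicodedata.category(c).startswith("P"):
            if current:
                words.append("".join(current))
                current = []
        else:
            current.append(c)
    if current:
        words.append("".join(current))
    return words


def _match_oracle(tokens, phrase: KeyPhrase):
    """Enumerate every increasing index tuple; feasible = tokens match the
    phrase words with each consecutive gap <= max_gap.  Returns
    (matched, gap-of-lexicographically-first-tuple)."""
    n, m = len(tokens), len(phrase.words)
    best = None
    for combo in itertools.combinations(range(n), m):
        if any(tokens[i] != w for i, w in zip(combo, phrase.words)):
            continue
        if any(b - a - 1 > phrase.max_gap for a, b in zip(combo, combo[1:])):
            continue
        best = combo  # combinations iterate lexicographically; keep first
        break
    if best is None:
        return False, None
    return True, best[-1] - best[0] - (m - 1)


# --- tokenization ----------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Neck Pain, revisited!", ["neck", "pain", "revisited"]),
        ("", []),
        ("whiplash-associated disorders", ["whiplash", "associated", "disorders"]),
        ("  spaced\tout \n", ["spaced", "out"]),
    ],
)
def test_normalize_tokens_examples(text, expected):
    assert normalize_tokens(text) == expected


@given(st.text(alphabet=st.characters(codec="ascii"), max_size=80))
@settings(max_examples=300, deadline=None)
def test_normalize_tokens_matches_character_walk_oracle(text):
    assert normalize_tokens(text) == _tokens_oracle(text)


# --- phrase matching -------------------------------------------------------


def test_worked_guideline_title_matches_cervical_pain_with_gap_two():
    tokens = normalize_tokens(GUIDELINE_TITLE)
    result = phrase_match(tokens, KeyPhrase(("cervical", "pain")))
    assert result.matched and result.gap == 2
    assert [tokens[i] for i in result.positions] == ["cervical", "pain"]


@pytest.mark.parametrize(
    "tokens,words,matched,gap",
    [
        (["chronic", "neck", "pain"], ("neck", "pain"), True, 0),
        (["cervical", "a", "b", "c", "d", "pain"], ("cervical", "pain"), False, None),
        (["cervical", "a", "b", "c", "pain"], ("cervical", "pain"), True, 3),
        (["pain", "neck"], ("neck", "pain"), False, None),  # order-sensitive
        ([], ("neck", "pain"), False, None),
    ],
)
def test_phrase_match_boundaries(tokens, words, matched, gap):
    result = phrase_match(tokens, KeyPhrase(words))
    assert result.matched is matched
    assert result.gap == gap


def test_phrase_match_backtracks_past_dead_end_occurrence():
    # first "b" satisfies the gap from "a" but strands "c"; the match must
    # be found through the second "b"
    result = phrase_match(["a", "b", "b", "x", "c"], KeyPhrase(("a", "b", "c"), max_gap=1))
    assert result.matched and result.positions == (0, 2, 4)


def test_phrase_match_positions_strictly_increasing_and_gap_bounded():
    result = phrase_match(["neck", "x", "neck", "pain"], KeyPhrase(("neck", "pain")))
    assert result.matched
    assert list(result.positions) == sorted(set(result.positions))
    assert result.gap <= 3


@given(
    tokens=st.lists(st.sampled_from(["x", "neck", "pain", "cervical"]), max_size=20),
    words=st.sampled_from([("neck", "pain"), ("cervical", "pain"), ("neck", "pain", "cervical")]),
    max_gap=st.integers(min_value=0, max_value=4),
)
@settings(max_examples=500, deadline=None)
def test_phrase_match_equals_exhaustive_pair_oracle(tokens, words, max_gap):
    phrase = KeyPhrase(words, max_gap=max_gap)
    result = phrase_match(tokens, phrase)
    matched, gap = _match_oracle(tokens, phrase)
    assert result.matched == matched
    assert result.gap == gap


def test_keyphrase_validation():
    with pytest.raises(ValueError):
        KeyPhrase(("single",))
    with pytest.raises(ValueError):
        KeyPhrase(("neck", "pain"), max_gap=-1)
    with pytest.raises(ValueError):
        KeyPhrase(("neck pain", "x"))


# --- record screening ------------------------------------------------------


def test_screen_record_uses_title_and_abstract():
    assert screen_record(RawRecord(id="1", title=GUIDELINE_TITLE))
    assert screen_record(RawRecord(id="2", title="irrelevant", abstract="chronic neck pain cohort"))
    assert not screen_record(RawRecord(id="3", title="unrelated cardiology study"))


def test_screening_is_monotone_in_the_phrase_list():
    rec = RawRecord(id="1", title="lumbar back pain study")
    base = [KeyPhrase(("cervical", "pain"))]
    assert not screen_record(rec, base)
    assert screen_record(rec, base + [KeyPhrase(("back", "pain"))])


@given(st.lists(st.sampled_from(["x", "y", "neck", "pain", "back"]), min_size=1, max_size=12),
       st.lists(st.sampled_from(["x", "neck", "pain", "back"]), max_size=30))
@settings(max_examples=200, deadline=None)
def test_screen_record_is_or_of_field_matches(title_toks, abstract_toks):
    rec = RawRecord(id="r", title=" ".join(title_toks), abstract=" ".join(abstract_toks))
    expected = any(
        _match_oracle(toks, p)[0]
        for p in DEFAULT_PHRASES
        for toks in (title_toks, abstract_toks)
    )
    assert screen_record(rec) == expected


# --- deduplication and filtering ------------------------------------------


def test_deduplicate_by_id_then_normalized_title():
    records = [
        RawRecord(id="1", title="Neck pain study"),
        RawRecord(id="1", title="Something else"),  # same id
        RawRecord(id="2", title="neck pain, study!"),  # same normalized title
        RawRecord(id="3", title="A different study"),
    ]
    kept = deduplicate(records)
    assert [r.id for r in kept] == ["1", "3"]


def test_deduplicate_identity_on_distinct_records():
    records = [RawRecord(id=str(i), title=f"title {i}") for i in range(5)]
    assert deduplicate(records) == records


@given(st.lists(st.integers(min_value=0, max_value=20), max_size=60))
@settings(max_examples=200, deadline=None)
def test_deduplicate_size_equals_distinct_key_count(keys):
    records = [RawRecord(id=f"id{k}", title=f"title {k}") for k in keys]
    assert len(deduplicate(records)) == len(set(keys))


def test_filter_journal_info_membership():
    records = [RawRecord(id=str(i), title="t", journal_id=j) for i, j in
               enumerate(["a", "b", None, "c"])]
    table = {"a": object(), "c": object()}
    kept = filter_journal_info(records, table)
    assert [r.journal_id for r in kept] == ["a", "c"]
    assert filter_journal_info(records, {}) == []


# --- labelling -------------------------------------------------------------


def _records(n):
    return [RawRecord(id=f"r{i}", title=f"t {i}", journal_id="j") for i in range(n)]


def test_assign_labels_partition():
    records = _records(10)
    pos = {"r0", "r3"}
    articles = assign_labels(records, pos)
    assert sum(a.label for a in articles) == 2
    assert len(articles) == 10
    assert all(a.label == (1 if a.id in pos else 0) for a in articles)


def test_assign_labels_extremes_and_unknown_warning():
    records = _records(4)
    assert all(a.label == 1 for a in assign_labels(records, {r.id for r in records}))
    assert all(a.label == 0 for a in assign_labels(records, set()))
    with pytest.warns(UserWarning, match="positive id"):
        assign_labels(records, {"r0", "ghost"})


def test_assign_labels_at_published_set_sizes():
    # |A| = 27,406 = |B| + |C| with 1,005 positives and 26,401 negatives
    records = _records(27_406)
    positives = {f"r{i}" for i in range(1_005)}
    articles = assign_labels(records, positives)
    n_pos = sum(a.label for a in articles)
    n_neg = sum(1 - a.label for a in articles)
    assert (n_pos, n_neg) == (1_005, 26_401)
    assert n_pos + n_neg == len(articles)


# --- downsampling ----------------------------------------------------------


def _labelled(n_pos, n_neg):
    arts = [Article(id=f"p{i}", title="t", abstract="", journal_id="j", label=1)
            for i in range(n_pos)]
    arts += [Article(id=f"n{i}", title="t", abstract="", journal_id="j", label=0)
             for i in range(n_neg)]
    return arts


def test_downsample_smallest_exact_three_to_seven():
    out = downsample_negatives(_labelled(3, 20), target_pos_frac=0.3, seed=0)
    assert sum(a.label for a in out) == 3
    assert sum(1 - a.label for a in out) == 7


def test_downsample_deterministic_and_contained():
    arts = _labelled(10, 100)
    a = downsample_negatives(arts, 0.3, seed=5)
    b = downsample_negatives(arts, 0.3, seed=5)
    c = downsample_negatives(arts, 0.3, seed=6)
    assert [x.id for x in a] == [x.id for x in b]
    assert [x.id for x in a] != [x.id for x in c]
    pool = {x.id for x in arts}
    assert {x.id for x in a} <= pool and {x.id for x in c} <= pool
    # positives untouched, no duplicates
    assert sum(x.label for x in a) == 10
    assert len({x.id for x in a}) == len(a)


def test_downsample_insufficient_negatives_error_names_counts():
    with pytest.raises(ValueError, match="7"):
        downsample_negatives(_labelled(3, 5), 0.3, seed=0)


def test_downsample_rejects_bad_fraction_and_no_positives():
    with pytest.raises(ValueError):
        downsample_negatives(_labelled(3, 20), 0.0)
    only_negatives = [Article(id="n0", title="t", abstract="", journal_id="j", label=0)]
    with pytest.raises(ValueError):
        downsample_negatives(only_negatives, 0.3)


# --- word frequencies ------------------------------------------------------


def test_word_frequencies_counts_and_tie_break():
    arts = [Article(id="1", title="neck pain neck", abstract="", journal_id="j", label=0)]
    assert word_frequencies(arts, k=10) == [("neck", 2), ("pain", 1)]
    # tie broken lexicographically
    arts2 = [Article(id="1", title="zeta alpha", abstract="", journal_id="j", label=0)]
    assert word_frequencies(arts2, k=2) == [("alpha", 1), ("zeta", 1)]


@given(st.lists(st.sampled_from("abcde"), min_size=1, max_size=50))
@settings(max_examples=100, deadline=None)
def test_word_frequencies_equals_hash_map_oracle(tokens):
    arts = [Article(id="1", title=" ".join(tokens), abstract="", journal_id="j", label=0)]
    counts = {}
    for t in tokens:
        counts[t] = counts.get(t, 0) + 1
    expected = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    assert word_frequencies(arts, k=len(counts)) == expected
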