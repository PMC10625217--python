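"""Synthetic corpora with the statistical structure the screener assumes.

Every generated record passes the default key-phrase screen by
construction: its title embeds one of the five default phrases with 0–3
filler words between the phrase words.  Positive articles additionally
carry discriminative signal tokens — separate pools for titles and
abstracts, so each text field contributes independent evidence — with the
configured probability; negatives never use that vocabulary, making the
default corpus cleanly separable.  Journal metrics are right-skewed (log-normal around a
per-journal latent quality), shifted upward for positives by
``journal_effect`` standard deviations on the log scale, with better
(lower) zones favoured for positives.  Text is emitted as token sequences,
not prose: every consumer tokenizes anyway.

With ``signal_strength=0`` and ``journal_effect=0`` the label carries no
information at all (the null generator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import DEFAULT_PHRASES, KeyPhrase, RawRecord
from .encoders import AttentionParams
from .journals import IF_YEARS, JournalRecord

__all__ = ["SynthConfig", "generate_corpus", "generate_attention_fixture"]

_TITLE_SIGNAL = tuple(f"randomized{i}" for i in range(6))
_ABSTRACT_SIGNAL = tuple(f"cohort{i}" for i in range(6))

_ZONE_BASE = np.full(4, 0.25)
_ZONE_GOOD = np.array([0.4, 0.3, 0.2, 0.1])
_ZONE_POOR = np.array([0.1, 0.2, 0.3, 0.4])


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``signal_strength`` is the probability that a positive article's title
    (and, independently, abstract) contains discriminative tokens;
    ``journal_effect`` is the mean upward shift, in log-scale standard
    deviations, of the positive journals' metrics.
    """

    n_pos: int = 180
    n_neg: int = 420
    vocab_size: int = 500
    signal_strength: float = 0.9
    journal_effect: float = 1.5
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.vocab_size < 20:
            raise ValueError("vocabulary too small: need at least 20 filler words")
        for name in ("signal_strength", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.journal_effect < 0:
            raise ValueError("journal_effect must be >= 0")


def _phrase_tokens(phrase: KeyPhrase, fillers: np.ndarray, rng: np.random.Generator) -> list[str]:
    """The phrase words with 0..max_gap random fillers between each pair."""
    out = [phrase.words[0]]
    for word in phrase.words[1:]:
        gap = int(rng.integers(0, phrase.max_gap + 1))
        out.extend(rng.choice(fillers, size=gap).tolist())
        out.append(word)
    return out


def _text(
    rng: np.random.Generator,
    fillers: np.ndarray,
    length: int,
    signal_pool: tuple[str, ...],
    signal_prob: float,
    with_phrase: bool,
) -> str:
    tokens = rng.choice(fillers, size=length).tolist()
    if signal_prob > 0 and rng.random() < signal_prob:
        # discriminative vocabulary scales with text length, as method/quality
        # terms recur throughout real abstracts
        n_signal = 3 + length // 10
        for tok in rng.choice(signal_pool, size=n_signal).tolist():
            tokens.insert(int(rng.integers(0, len(tokens) + 1)), tok)
    if with_phrase:
        # inserted last so nothing can widen the phrase's internal gaps
        phrase = DEFAULT_PHRASES[int(rng.integers(len(DEFAULT_PHRASES)))]
        pos = int(rng.integers(0, len(tokens) + 1))
        tokens[pos:pos] = _phrase_tokens(phrase, fillers, rng)
    return " ".join(tokens)


def _journal(
    journal_id: str, positive: bool, cfg: SynthConfig, rng: np.random.Generator
) -> JournalRecord:
    """One journal; each metric family's log value is shifted upward by
    ``journal_effect`` standard deviations for positives.

    A shared latent gives the families a cross-correlation of 0.5 (journal
    metrics co-vary but are not redundant), so the shift is planted per
    family, not once globally.
    """
    shift = cfg.journal_effect if positive else 0.0
    shared = rng.normal()

    def family_z() -> float:
        # mean `shift`, sd 1, correlation 0.5 across families
        return shift + (shared + rng.normal()) / np.sqrt(2.0)

    def maybe(v):
        return None if rng.random() < cfg.missing_rate else v

    z_if = family_z()
    if_by_year = {
        y: v
        for y in IF_YEARS
        if (v := maybe(round(float(np.exp(0.8 + 0.5 * (z_if + 0.15 * rng.normal()))), 3)))
        is not None
    }
    tilt = min(cfg.journal_effect, 2.0) / 2.0
    probs = (1 - tilt) * _ZONE_BASE + tilt * (_ZONE_GOOD if positive else _ZONE_POOR)
    zone = maybe(int(rng.choice(4, p=probs)) + 1)
    return JournalRecord(
        journal_id=journal_id,
        if_by_year=if_by_year,
        cite_score=maybe(round(float(np.exp(1.0 + 0.5 * family_z())), 3)),
        sjr=maybe(round(float(np.exp(0.0 + 0.6 * family_z())), 3)),
        snip=maybe(round(float(np.exp(0.2 + 0.4 * family_z())), 3)),
        zone=zone,
        h_index=maybe(int(np.exp(3.0 + 0.6 * family_z()))),
    )


def generate_corpus(
    config: SynthConfig = SynthConfig(),
) -> tuple[list[RawRecord], set[str], dict[str, JournalRecord]]:
    """Generate (records, positive ids, journal table); pure in config+seed.

    Records are shuffled so labels are not inferable from position.  Each
    record has its own journal.
    """
    rng = np.random.default_rng(config.seed)
    fillers = np.array([f"w{i:04d}" for i in range(config.vocab_size)])
    n = config.n_pos + config.n_neg
    flags = np.array([True] * config.n_pos + [False] * config.n_neg)
    rng.shuffle(flags)

    records: list[RawRecord] = []
    positive_ids: set[str] = set()
    journals: dict[str, JournalRecord] = {}
    for i, positive in enumerate(flags):
        rid = f"A{i:05d}"
        jid = f"J{i:05d}"
        sig = config.signal_strength if positive else 0.0
        title = _text(rng, fillers, int(rng.integers(6, 13)), _TITLE_SIGNAL, sig, with_phrase=True)
        abstract = _text(
            rng, fillers, int(rng.integers(30, 61)), _ABSTRACT_SIGNAL, sig, with_phrase=False
        )
        records.append(RawRecord(id=rid, title=title, abstract=abstract, journal_id=jid))
        journals[jid] = _journal(jid, bool(positive), config, rng)
        if positive:
            positive_ids.add(rid)
    return records, positive_ids, journals


def generate_attention_fixture(
    s: int, d: int, seed: int = 0
) -> tuple[np.ndarray, AttentionParams]:
    """A small-integer batch matrix and attention projections for
    hand-checkable oracles; pure in (s, d, seed)."""
    if s < 1 or d < 1:
        raise ValueError("s and d must be >= 1")
    rng = np.random.default_rng(seed)
    r = rng.integers(-2, 3, size=(s, d)).astype(float)
    params = AttentionParams(
        wq=rng.integers(-2, 3, size=(d, d)).astype(float),
        wk=rng.integers(-2, 3, size=(d, d)).astype(float),
        wv=rng.integers(-2, 3, size=(d, d)).astype(float),
    )
    return r, params
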