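"""Journal bibliometric features.

Encodes per-journal quality metrics — impact factor by year (2015–2021),
CiteScore, SJR, SNIP, citation-report zone (1–4) and H-index — into the
fixed-length numeric vector consumed by the classifier.  Continuous metrics
are z-scored with statistics learned on the training split; missing values
are median-imputed with per-family missingness flags; the zone is one-hot
encoded with an explicit "unknown" category.

Vector layout (length 21, fixed):
  [0:7]   IF 2015..2021, z-scored
  [7]     CiteScore, z-scored
  [8]     SJR, z-scored
  [9]     SNIP, z-scored
  [10]    H-index, z-scored
  [11:16] zone one-hot: zones 1..4, then "unknown"
  [16:21] missingness flags for the families IF, CS, SJR, SNIP, H-index
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .corpus import Article

__all__ = [
    "JournalRecord",
    "FeatureScaler",
    "IF_YEARS",
    "CONTINUOUS_FEATURES",
    "FAMILIES",
    "VECTOR_LENGTH",
    "encode_zone",
    "fit_scaler",
    "transform",
    "journal_vector",
    "feature_value",
    "summarize_by_label",
]

IF_YEARS: tuple[int, ...] = tuple(range(2015, 2022))

#: Continuous feature names in vector order.
CONTINUOUS_FEATURES: tuple[str, ...] = tuple(f"if_{y}" for y in IF_YEARS) + (
    "cite_score",
    "sjr",
    "snip",
    "h_index",
)

#: Metric families, each contributing one missingness flag.
FAMILIES: dict[str, tuple[str, ...]] = {
    "if": tuple(f"if_{y}" for y in IF_YEARS),
    "cite_score": ("cite_score",),
    "sjr": ("sjr",),
    "snip": ("snip",),
    "h_index": ("h_index",),
}

ZONE_WIDTH = 5  # zones 1..4 plus "unknown"
VECTOR_LENGTH = len(CONTINUOUS_FEATURES) + ZONE_WIDTH + len(FAMILIES)


@dataclass(frozen=True)
class JournalRecord:
    """Bibliometric metrics of one journal; any metric may be missing (None)."""

    journal_id: str
    if_by_year: Mapping[int, float] = field(default_factory=dict)
    cite_score: Optional[float] = None
    sjr: Optional[float] = None
    snip: Optional[float] = None
    zone: Optional[int] = None
    h_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.journal_id:
            raise ValueError("journal_id must be non-empty")
        if self.zone is not None and self.zone not in (1, 2, 3, 4):
            raise ValueError(
                f"journal {self.journal_id!r}: zone must be in 1..4, got {self.zone!r}"
            )


def feature_value(record: JournalRecord, name: str) -> Optional[float]:
    """Value of one continuous feature, or None when missing."""
    if name.startswith("if_"):
        v = record.if_by_year.get(int(name[3:]))
    else:
        v = getattr(record, name)
    return None if v is None else float(v)


def encode_zone(zone: Optional[int]) -> np.ndarray:
    """One-hot encode the citation-report zone; missing -> the 5th slot."""
    vec = np.zeros(ZONE_WIDTH)
    if zone is None:
        vec[4] = 1.0
    elif zone in (1, 2, 3, 4):
        vec[zone - 1] = 1.0
    else:
        raise ValueError(f"zone must be in 1..4 or missing, got {zone!r}")
    return vec


@dataclass
class FeatureScaler:
    """Per-feature z-scoring statistics learned on the training split.

    ``means``/``sds`` use non-missing training values only (sample sd,
    ddof=1); ``medians`` are the imputation values.  Features that are
    constant or entirely missing in training are flagged and transform to
    zero.
    """

    means: dict[str, float]
    sds: dict[str, float]
    medians: dict[str, float]
    zero_variance: set[str]
    dropped: set[str]

    def to_dict(self) -> dict:
        return {
            "means": self.means,
            "sds": self.sds,
            "medians": self.medians,
            "zero_variance": sorted(self.zero_variance),
            "dropped": sorted(self.dropped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(
            means=dict(d["means"]),
            sds=dict(d["sds"]),
            medians=dict(d["medians"]),
            zero_variance=set(d["zero_variance"]),
            dropped=set(d["dropped"]),
        )


def fit_scaler(records: Sequence[JournalRecord]) -> FeatureScaler:
    """Learn z-scoring and imputation statistics from training journals."""
    if len(records) < 2:
        raise ValueError("fitting a scaler requires at least two journal records")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    medians: dict[str, float] = {}
    zero_variance: set[str] = set()
    dropped: set[str] = set()
    for name in CONTINUOUS_FEATURES:
        vals = np.array(
            [v for r in records if (v := feature_value(r, name)) is not None], dtype=float
        )
        if vals.size == 0:
            warnings.warn(f"feature {name!r} missing for all training journals; dropped")
            dropped.add(name)
            means[name], sds[name], medians[name] = 0.0, 0.0, 0.0
            continue
        means[name] = float(vals.mean())
        sds[name] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        medians[name] = float(np.median(vals))
        if sds[name] == 0.0:
            zero_variance.add(name)
    return FeatureScaler(means, sds, medians, zero_variance, dropped)


def transform(record: JournalRecord, scaler: FeatureScaler) -> np.ndarray:
    """Encode one journal as the fixed 21-length feature vector.

    Missing continuous values are imputed with the training median before
    z-scoring; the corresponding family flag is set.  Zero-variance or
    dropped features map to 0.
    """
    cont = np.zeros(len(CONTINUOUS_FEATURES))
    missing: dict[str, bool] = {name: False for name in CONTINUOUS_FEATURES}
    for idx, name in enumerate(CONTINUOUS_FEATURES):
        v = feature_value(record, name)
        if v is None:
            missing[name] = True
            v = scaler.medians[name]
        if name in scaler.dropped or name in scaler.zero_variance:
            cont[idx] = 0.0
        else:
            cont[idx] = (v - scaler.means[name]) / scaler.sds[name]
    flags = np.array(
        [1.0 if any(missing[m] for m in members) else 0.0 for members in FAMILIES.values()]
    )
    vec = np.concatenate([cont, encode_zone(record.zone), flags])
    assert vec.shape == (VECTOR_LENGTH,)
    return vec


def journal_vector(
    journal_id: str, table: Mapping[str, JournalRecord], scaler: FeatureScaler
) -> np.ndarray:
    """Feature vector for a journal looked up by id; unknown id is an error."""
    try:
        record = table[journal_id]
    except KeyError:
        raise KeyError(f"journal {journal_id!r} not present in the journal table") from None
    return transform(record, scaler)


def summarize_by_label(
    articles: Sequence[Article], table: Mapping[str, JournalRecord]
) -> dict[str, dict[int, dict[str, float]]]:
    """Boxplot statistics of each continuous journal feature per label class.

    Returns ``{feature: {label: {"whisker_lo", "q1", "median", "q3",
    "whisker_hi"}}}`` using Tukey whiskers (most extreme values within
    1.5 IQR of the quartiles).  Missing metric values are excluded.
    """
    by_label: dict[int, list[JournalRecord]] = {0: [], 1: []}
    for a in articles:
        by_label[a.label].append(table[a.journal_id])
    for label, recs in by_label.items():
        if not recs:
            raise ValueError(f"no articles with label {label}; cannot summarize")
    out: dict[str, dict[int, dict[str, float]]] = {}
    for name in CONTINUOUS_FEATURES:
        out[name] = {}
        for label, recs in by_label.items():
            vals = np.array(
                [v for r in recs if (v := feature_value(r, name)) is not None], dtype=float
            )
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            inside = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
            out[name][label] = {
                "whisker_lo": float(inside.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "whisker_hi": float(inside.max()),
            }
    return out
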