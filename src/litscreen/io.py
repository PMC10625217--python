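"""Reading and writing the standard input/output files.

Formats:
* records — JSONL (one object per line with keys id, title, abstract,
  journal_id) or CSV with the same header; UTF-8.
* journal table — CSV with columns journal_id, if_2015..if_2021,
  cite_score, sjr, snip, zone, h_index; empty cells mean missing.
* positive ids — newline-delimited text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .corpus import Article, RawRecord
from .journals import IF_YEARS, JournalRecord

__all__ = [
    "read_records",
    "write_records_jsonl",
    "read_articles",
    "write_articles_jsonl",
    "read_journal_table",
    "write_journal_table",
    "read_positive_ids",
    "write_positive_ids",
]

PathLike = Union[str, Path]


def _record_dicts(path: PathLike) -> list[dict]:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return df.to_dict(orient="records")
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    return rows


def read_records(path: PathLike) -> list[RawRecord]:
    """Load raw records from JSONL (default) or CSV (by extension)."""
    out = []
    for row in _record_dicts(path):
        jid = row.get("journal_id") or None
        out.append(
            RawRecord(
                id=str(row["id"]),
                title=str(row.get("title", "")),
                abstract=str(row.get("abstract", "") or ""),
                journal_id=None if jid is None else str(jid),
            )
        )
    return out


def write_records_jsonl(records: Iterable[RawRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {"id": r.id, "title": r.title, "abstract": r.abstract, "journal_id": r.journal_id}
                )
                + "\n"
            )


def read_articles(path: PathLike) -> list[Article]:
    """Load labelled articles (JSONL/CSV with an extra ``label`` column)."""
    return [
        Article(
            id=str(row["id"]),
            title=str(row["title"]),
            abstract=str(row.get("abstract", "") or ""),
            journal_id=str(row["journal_id"]),
            label=int(row["label"]),
        )
        for row in _record_dicts(path)
    ]


def write_articles_jsonl(articles: Iterable[Article], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in articles:
            fh.write(
                json.dumps(
                    {
                        "id": a.id,
                        "title": a.title,
                        "abstract": a.abstract,
                        "journal_id": a.journal_id,
                        "label": a.label,
                    }
                )
                + "\n"
            )


def read_journal_table(path: PathLike) -> dict[str, JournalRecord]:
    """Load the journal-metrics CSV keyed by journal_id."""
    df = pd.read_csv(path)
    table: dict[str, JournalRecord] = {}

    def cell(row, name):
        v = row.get(name)
        return None if v is None or pd.isna(v) else v

    for _, row in df.iterrows():
        jid = str(row["journal_id"])
        if_by_year = {
            y: float(v) for y in IF_YEARS if (v := cell(row, f"if_{y}")) is not None
        }
        zone = cell(row, "zone")
        h = cell(row, "h_index")
        table[jid] = JournalRecord(
            journal_id=jid,
            if_by_year=if_by_year,
            cite_score=None if (v := cell(row, "cite_score")) is None else float(v),
            sjr=None if (v := cell(row, "sjr")) is None else float(v),
            snip=None if (v := cell(row, "snip")) is None else float(v),
            zone=None if zone is None else int(zone),
            h_index=None if h is None else int(h),
        )
    return table


def write_journal_table(table: Mapping[str, JournalRecord], path: PathLike) -> None:
    rows = []
    for jid, rec in table.items():
        row: dict = {"journal_id": jid}
        for y in IF_YEARS:
            row[f"if_{y}"] = rec.if_by_year.get(y)
        row.update(
            cite_score=rec.cite_score, sjr=rec.sjr, snip=rec.snip, zone=rec.zone,
            h_index=rec.h_index,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_positive_ids(path: PathLike) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_positive_ids(ids: Iterable[str], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in sorted(ids):
            fh.write(i + "\n")
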