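"""Corpus ingestion, cleaning, and rule-based extraction of "future
directions" text.

The corpus dialect mirrors the open COVID-19 literature releases: a metadata
CSV (one row per paper) plus one JSON document per full-text paper holding the
ordered body paragraphs with their section names.  Cleaning keeps English,
2020-or-later, full-text, non-duplicate records, and every dropped row is
audited with a single reason code.

Extraction combines a position rule (the closing paragraph of the paper, where
authors conventionally state follow-up work) with a keyword rule (trigger
phrases such as "future work" or "prospective" anywhere in the terminal
section).  A unit is emitted only when a candidate paragraph actually contains
a trigger phrase; which rule fired is recorded so extraction behaviour can be
audited against labeled samples via precision/recall/F1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import CorpusFormatError

METADATA_COLUMNS = [
    "doc_id",
    "title",
    "abstract",
    "publish_date",
    "language",
    "journal",
    "authors",
    "has_full_text",
]

#: Trigger phrases for the keyword rule.  Configurable; matched
#: case-insensitively as substrings after whitespace normalization.
DEFAULT_KEYWORDS = (
    "future directions",
    "future work",
    "future research",
    "future studies",
    "future step",
    "prospective",
    "we plan",
)

DROP_REASONS = ("duplicate", "non_english", "pre_2020", "no_full_text")

#: Records published before this date are outside the observation window.
WINDOW_START = date(2020, 1, 1)


@dataclass
class DocumentRecord:
    """One publication: metadata plus ordered body paragraphs."""

    doc_id: str
    title: str
    abstract: str
    publish_date: Optional[date]
    language: str
    journal: str
    authors: list[str]
    body: list[tuple[str, str]]  # (section_name, paragraph_text), in order
    has_full_text: bool
    date_flagged: bool = False  # unparseable publish_date; kept, not dropped


@dataclass
class FutureDirectionsUnit:
    """Extracted future-directions text for one document."""

    doc_id: str
    text: str
    matched_rule: str  # "position" | "keyword" | "both"
    matched_keywords: list[str] = field(default_factory=list)


@dataclass
class ExtractionScore:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


def _parse_date(value: str) -> tuple[Optional[date], bool]:
    """Return (date, flagged).  Month precision is sufficient; 'YYYY-MM' maps
    to the first of the month."""
    text = str(value).strip()
    if not text:
        return None, True
    ts = pd.to_datetime(text, errors="coerce")
    if pd.isna(ts):
        return None, True
    return ts.date(), False


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in {"true", "1", "yes", "y"}


def _load_fulltext(fulltext_source, doc_id: str) -> Optional[dict]:
    if fulltext_source is None:
        return None
    if isinstance(fulltext_source, Mapping):
        return fulltext_source.get(doc_id)
    path = Path(fulltext_source) / f"{doc_id}.json"
    if not path.exists():
        return None
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def load_corpus(
    metadata_source,
    fulltext_source=None,
    *,
    dedup: str = "doc_id",
) -> list[DocumentRecord]:
    """Load a corpus from a metadata table plus a full-text document store.

    Parameters
    ----------
    metadata_source
        CSV path or file-like object with the columns in
        :data:`METADATA_COLUMNS`.
    fulltext_source
        Directory of ``<doc_id>.json`` files or a mapping ``doc_id -> record``
        where each record is ``{"doc_id": ..., "body_text": [{"section": ...,
        "text": ...}, ...]}``.
    dedup
        ``"doc_id"`` (default) keeps the first occurrence of each doc_id;
        ``"none"`` keeps every row so that downstream cleaning can audit
        duplicates.

    Records whose date fails to parse are flagged (``date_flagged``) rather
    than dropped.  A record whose metadata claims full text but that has no
    body document is loaded with ``has_full_text=False``.
    """
    if dedup not in ("doc_id", "none"):
        raise ValueError(f"unknown dedup policy {dedup!r}")
    meta = pd.read_csv(metadata_source, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise CorpusFormatError(f"metadata is missing mandatory columns: {missing}")

    records: list[DocumentRecord] = []
    seen_ids: set[str] = set()
    for row in meta.itertuples(index=False):
        doc_id = str(row.doc_id)
        if dedup == "doc_id" and doc_id in seen_ids:
            continue
        seen_ids.add(doc_id)
        publish_date, flagged = _parse_date(row.publish_date)
        body: list[tuple[str, str]] = []
        if _parse_bool(row.has_full_text):
            doc = _load_fulltext(fulltext_source, doc_id)
            if doc is not None:
                body = [(p["section"], p["text"]) for p in doc.get("body_text", [])]
        authors = [a for a in str(row.authors).split(";") if a]
        records.append(
            DocumentRecord(
                doc_id=doc_id,
                title=str(row.title),
                abstract=str(row.abstract),
                publish_date=publish_date,
                language=str(row.language),
                journal=str(row.journal),
                authors=authors,
                body=body,
                has_full_text=bool(body),
                date_flagged=flagged,
            )
        )
    return records


def clean_corpus(
    records: Sequence[DocumentRecord],
    *,
    window_start: date = WINDOW_START,
) -> tuple[list[DocumentRecord], pd.DataFrame]:
    """Apply the cleaning rules and return ``(kept, dropped_audit)``.

    Kept records are English, dated on/after ``window_start``, have full text,
    and are not duplicates.  Duplicates are detected by doc_id first and by
    exact (title, abstract) pair second; the first occurrence wins.  The audit
    table has columns ``doc_id,reason`` with one reason per dropped record
    (precedence: duplicate, non_english, pre_2020, no_full_text).  Records
    with an unparseable date fall outside the window and are dropped as
    pre_2020.  Cleaning is total and idempotent.
    """
    kept: list[DocumentRecord] = []
    dropped: list[tuple[str, str]] = []
    seen_ids: set[str] = set()
    seen_meta: set[tuple[str, str]] = set()
    for rec in records:
        meta_key = (rec.title, rec.abstract)
        if rec.doc_id in seen_ids or meta_key in seen_meta:
            dropped.append((rec.doc_id, "duplicate"))
            continue
        seen_ids.add(rec.doc_id)
        seen_meta.add(meta_key)
        if rec.language != "en":
            dropped.append((rec.doc_id, "non_english"))
        elif rec.publish_date is None or rec.publish_date < window_start:
            dropped.append((rec.doc_id, "pre_2020"))
        elif not rec.has_full_text:
            dropped.append((rec.doc_id, "no_full_text"))
        else:
            kept.append(rec)
    audit = pd.DataFrame(dropped, columns=["doc_id", "reason"])
    return kept, audit


def _normalize_ws(text: str) -> str:
    return " ".join(text.split())


def extract_future_directions(
    record: DocumentRecord,
    keywords: Iterable[str] = DEFAULT_KEYWORDS,
) -> Optional[FutureDirectionsUnit]:
    """Extract the future-directions text of one full-text record.

    Candidate paragraphs are the final body paragraph (position rule) plus any
    paragraph of the terminal section — the last named section of the body —
    that contains a trigger keyword.  A unit is returned iff at least one
    candidate contains a keyword (case-insensitive substring over
    whitespace-normalized text); the unit concatenates the matching candidates
    in document order.  ``matched_rule`` is ``"both"`` when the final
    paragraph itself matched, ``"keyword"`` when only earlier terminal-section
    paragraphs matched.
    """
    if not record.has_full_text or not record.body:
        raise ValueError(f"record {record.doc_id} has no full text")
    kws = [k.casefold() for k in keywords]
    if not kws:
        raise ValueError("keyword list must be non-empty")

    terminal_section = record.body[-1][0]
    last_idx = len(record.body) - 1
    matches: list[tuple[int, str, list[str]]] = []  # (index, text, keywords hit)
    for idx, (section, text) in enumerate(record.body):
        if idx != last_idx and section != terminal_section:
            continue
        norm = _normalize_ws(text).casefold()
        hit = [k for k in kws if k in norm]
        if hit:
            matches.append((idx, _normalize_ws(text), hit))
    if not matches:
        return None
    matched_keywords = sorted({k for _, _, hit in matches for k in hit})
    rule = "both" if any(idx == last_idx for idx, _, _ in matches) else "keyword"
    return FutureDirectionsUnit(
        doc_id=record.doc_id,
        text=" ".join(text for _, text, _ in matches),
        matched_rule=rule,
        matched_keywords=matched_keywords,
    )


def extract_corpus(
    records: Sequence[DocumentRecord],
    keywords: Iterable[str] = DEFAULT_KEYWORDS,
) -> list[FutureDirectionsUnit]:
    """Apply :func:`extract_future_directions` to every full-text record,
    skipping documents where no rule fires."""
    units = []
    for rec in records:
        if not rec.has_full_text:
            continue
        unit = extract_future_directions(rec, keywords)
        if unit is not None:
            units.append(unit)
    return units


def evaluate_extraction(
    predicted: set[str],
    gold: set[str],
    universe: set[str],
) -> ExtractionScore:
    """Precision/recall/F1 of predicted extractions against a gold labeling.

    Degenerate conventions (documented): precision = 1 when nothing was
    predicted, recall = 1 when the gold set is empty, F1 = 0 when
    precision + recall = 0.
    """
    predicted, gold = set(predicted), set(gold)
    if not predicted <= universe:
        raise ValueError("predicted ids outside the evaluation universe")
    if not gold <= universe:
        raise ValueError("gold ids outside the evaluation universe")
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    precision = tp / (tp + fp) if tp + fp > 0 else 1.0
    recall = tp / (tp + fn) if tp + fn > 0 else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return ExtractionScore(precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn)
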