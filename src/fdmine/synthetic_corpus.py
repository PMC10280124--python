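"""Synthetic labeled corpora with the statistical structure the pipeline
assumes.

Documents are bags of synthetic tokens (``topic3_word017``, ``bg_word0042``)
drawn from K pairwise-disjoint topic vocabularies plus a shared background
vocabulary, assembled into pseudo-sections ("Introduction", "Methods",
"Discussion") and a final future-directions paragraph carrying verbatim
trigger phrases from the extractor's default keyword list.  Per-month topic
mixtures follow a configurable trend table, so timeline and evolution analyses
have a planted ground truth.  Noise records — exact duplicates, non-English
papers (separate vocabulary AND a non-"en" language field), pre-2020 papers,
and abstract-only papers — are injected at configurable rates so every
cleaning rule has planted positives and negatives.

The generator defines the study conditions: the defaults are a 2020
January–September window, 7 topics, 100 documents per month, and a 0.9
topic-word fraction, matching the corpus regime the downstream defaults were
designed for.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .ingest_extract import DEFAULT_KEYWORDS, DocumentRecord

DEFAULT_MONTHS = tuple(f"2020-{m:02d}" for m in range(1, 10))

_NONENGLISH_LANGS = ("de", "es", "fr", "nl", "zh")
_JOURNALS = ("J Synth Med", "Synthetic Lancet", "Proc Synth Acad", "PLoS Synth")


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic corpus draw.

    ``topic_trend`` is a (months x n_topics) row-stochastic table giving the
    probability that a document published in month m belongs to topic t; the
    default is uniform.  ``topic_word_fraction`` is the probability that a
    token is drawn from the document's topic vocabulary rather than the shared
    background vocabulary.  ``keyword_omission_rate`` is the chance that the
    final (genuine) future-directions paragraph carries no trigger phrase, so
    the extractor's keyword rule has planted misses.
    """

    n_topics: int = 7
    docs_per_month: int = 100
    months: Sequence[str] = DEFAULT_MONTHS
    topic_vocab_size: int = 250
    background_vocab_size: int = 600
    topic_word_fraction: float = 0.9
    doc_length_tokens: int = 80
    keyword_omission_rate: float = 0.0
    duplicate_rate: float = 0.0
    nonenglish_rate: float = 0.0
    pre2020_rate: float = 0.0
    abstract_only_rate: float = 0.0
    topic_trend: Optional[np.ndarray] = None  # rows = months, cols = topics
    seed: int = 0

    def validate(self) -> None:
        if self.n_topics < 1 or self.docs_per_month < 1:
            raise ConfigurationError("n_topics and docs_per_month must be positive")
        if len(self.months) == 0:
            raise ConfigurationError("month list must be non-empty")
        if self.topic_vocab_size < 1 or self.background_vocab_size < 1:
            raise ConfigurationError("vocabulary sizes must be positive")
        if self.doc_length_tokens < 1:
            raise ConfigurationError("doc_length_tokens must be positive")
        probs = {
            "topic_word_fraction": self.topic_word_fraction,
            "keyword_omission_rate": self.keyword_omission_rate,
            "duplicate_rate": self.duplicate_rate,
            "nonenglish_rate": self.nonenglish_rate,
            "pre2020_rate": self.pre2020_rate,
            "abstract_only_rate": self.abstract_only_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.topic_trend is not None:
            trend = np.asarray(self.topic_trend, dtype=float)
            if trend.shape != (len(self.months), self.n_topics):
                raise ConfigurationError(
                    f"topic_trend must be ({len(self.months)}, {self.n_topics}), "
                    f"got {trend.shape}"
                )
            if np.any(trend < 0) or np.any(np.abs(trend.sum(axis=1) - 1.0) > 1e-9):
                raise ConfigurationError("topic_trend rows must be non-negative and sum to 1")

    def trend_table(self) -> np.ndarray:
        if self.topic_trend is None:
            return np.full((len(self.months), self.n_topics), 1.0 / self.n_topics)
        return np.asarray(self.topic_trend, dtype=float)


@dataclass
class LabeledCorpus:
    """Generated records plus the planted ground truth.

    ``truth_topic`` is defined only for records that survive cleaning
    (``truth_keep`` true); ``truth_has_fd`` marks records with a genuine
    future-directions paragraph; ``noise_counts`` records exactly how many
    noise rows of each kind were injected.
    """

    records: list[DocumentRecord]
    truth_topic: dict[str, int]
    truth_has_fd: dict[str, bool]
    truth_keep: dict[str, bool]
    noise_counts: dict[str, int] = field(default_factory=dict)
    config: Optional[SyntheticConfig] = None


def topic_vocabulary(topic: int, size: int) -> list[str]:
    return [f"topic{topic}_word{j:03d}" for j in range(size)]


def background_vocabulary(size: int) -> list[str]:
    return [f"bg_word{j:04d}" for j in range(size)]


def _foreign_vocabulary(size: int) -> list[str]:
    return [f"xx_wort{j:03d}" for j in range(size)]


def _draw_tokens(rng, n, topic_vocab, bg_vocab, frac) -> list[str]:
    from_topic = rng.random(n) < frac
    tokens = np.where(
        from_topic,
        rng.choice(topic_vocab, size=n),
        rng.choice(bg_vocab, size=n),
    )
    return list(tokens)


def _make_body(rng, config, topic_vocab, bg_vocab, omit_keyword: bool) -> list[tuple[str, str]]:
    length = max(20, int(rng.poisson(config.doc_length_tokens)))
    fd_len = max(15, length // 4)
    rest = length - fd_len
    splits = [rest // 3, rest // 3, rest - 2 * (rest // 3)]
    body = []
    for section, n in zip(("Introduction", "Methods", "Discussion"), splits):
        toks = _draw_tokens(rng, max(1, n), topic_vocab, bg_vocab, config.topic_word_fraction)
        body.append((section, " ".join(toks)))
    fd_tokens = _draw_tokens(rng, fd_len, topic_vocab, bg_vocab, config.topic_word_fraction)
    if not omit_keyword:
        keyword = DEFAULT_KEYWORDS[rng.integers(len(DEFAULT_KEYWORDS))]
        pos = int(rng.integers(len(fd_tokens) + 1))
        fd_tokens = fd_tokens[:pos] + [keyword] + fd_tokens[pos:]
    body.append(("Conclusion", " ".join(fd_tokens)))
    return body


def _base_record(doc_id, month, language, journal, body, rng) -> DocumentRecord:
    year, mon = (int(x) for x in month.split("-"))
    day = int(rng.integers(1, 28))
    n_auth = int(rng.integers(1, 6))
    return DocumentRecord(
        doc_id=doc_id,
        title=f"Synthetic study {doc_id}",
        abstract=f"Abstract of synthetic study {doc_id}.",
        publish_date=date(year, mon, day),
        language=language,
        journal=journal,
        authors=[f"Author {doc_id}-{i}" for i in range(n_auth)],
        body=body,
        has_full_text=bool(body),
    )


def generate_corpus(config: SyntheticConfig) -> LabeledCorpus:
    """Generate a labeled corpus; fully reproducible for a fixed seed.

    Exactly ``docs_per_month`` clean records per month; each clean record's
    final paragraph is a genuine future-directions paragraph that carries a
    trigger phrase with probability ``1 - keyword_omission_rate``.  Noise rows
    are injected per-record at the configured Bernoulli rates, after the clean
    block, and counted exactly in ``noise_counts``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trend = config.trend_table()
    topic_vocabs = [topic_vocabulary(t, config.topic_vocab_size) for t in range(config.n_topics)]
    bg_vocab = background_vocabulary(config.background_vocab_size)
    foreign_vocab = _foreign_vocabulary(config.background_vocab_size)

    records: list[DocumentRecord] = []
    truth_topic: dict[str, int] = {}
    truth_has_fd: dict[str, bool] = {}
    truth_keep: dict[str, bool] = {}
    noise_counts = {"duplicate": 0, "non_english": 0, "pre_2020": 0, "abstract_only": 0}
    clean_records: list[DocumentRecord] = []
    serial = 0

    for m_idx, month in enumerate(config.months):
        for _ in range(config.docs_per_month):
            topic = int(rng.choice(config.n_topics, p=trend[m_idx]))
            omit = bool(rng.random() < config.keyword_omission_rate)
            body = _make_body(rng, config, topic_vocabs[topic], bg_vocab, omit)
            doc_id = f"syn{serial:06d}"
            serial += 1
            rec = _base_record(doc_id, month, "en", _JOURNALS[serial % len(_JOURNALS)], body, rng)
            clean_records.append(rec)
            truth_topic[doc_id] = topic
            truth_has_fd[doc_id] = True
            truth_keep[doc_id] = True
    records.extend(clean_records)

    # Noise rows: duplicates are exact copies of clean rows under the same id
    # (metadata-duplication dialect); the rest are fresh records that each
    # violate exactly one cleaning rule.
    noise_records: list[DocumentRecord] = []
    for rec in clean_records:
        if rng.random() < config.duplicate_rate:
            noise_records.append(rec)
            noise_counts["duplicate"] += 1
    n_clean = len(clean_records)
    months = list(config.months)

    def _random_month():
        return months[int(rng.integers(len(months)))]

    for _ in range(n_clean):
        if rng.random() < config.nonenglish_rate:
            lang = _NONENGLISH_LANGS[int(rng.integers(len(_NONENGLISH_LANGS)))]
            body = _make_body(rng, config, foreign_vocab, foreign_vocab, omit_keyword=True)
            doc_id = f"syn{serial:06d}"
            serial += 1
            rec = _base_record(doc_id, _random_month(), lang, _JOURNALS[0], body, rng)
            noise_records.append(rec)
            truth_has_fd[doc_id] = False
            truth_keep[doc_id] = False
            noise_counts["non_english"] += 1
    for _ in range(n_clean):
        if rng.random() < config.pre2020_rate:
            topic = int(rng.integers(config.n_topics))
            body = _make_body(rng, config, topic_vocabs[topic], bg_vocab, omit_keyword=False)
            doc_id = f"syn{serial:06d}"
            serial += 1
            month = f"2019-{int(rng.integers(1, 13)):02d}"
            rec = _base_record(doc_id, month, "en", _JOURNALS[1], body, rng)
            noise_records.append(rec)
            truth_has_fd[doc_id] = True
            truth_keep[doc_id] = False
            noise_counts["pre_2020"] += 1
    for _ in range(n_clean):
        if rng.random() < config.abstract_only_rate:
            doc_id = f"syn{serial:06d}"
            serial += 1
            rec = _base_record(doc_id, _random_month(), "en", _JOURNALS[2], [], rng)
            rec.has_full_text = False
            noise_records.append(rec)
            truth_has_fd[doc_id] = False
            truth_keep[doc_id] = False
            noise_counts["abstract_only"] += 1

    records.extend(noise_records)
    return LabeledCorpus(
        records=records,
        truth_topic=truth_topic,
        truth_has_fd=truth_has_fd,
        truth_keep=truth_keep,
        noise_counts=noise_counts,
        config=config,
    )


def write_corpus(corpus: LabeledCorpus, outdir) -> None:
    """Write the metadata CSV, per-document JSON files, and a truth table in
    the same dialect :func:`fdmine.ingest_extract.load_corpus` reads, so the
    synthetic corpus is a drop-in fixture."""
    outdir = Path(outdir)
    fulltext_dir = outdir / "fulltext"
    fulltext_dir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "metadata.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["doc_id", "title", "abstract", "publish_date", "language", "journal",
             "authors", "has_full_text"]
        )
        for rec in corpus.records:
            writer.writerow(
                [
                    rec.doc_id,
                    rec.title,
                    rec.abstract,
                    rec.publish_date.isoformat() if rec.publish_date else "",
                    rec.language,
                    rec.journal,
                    ";".join(rec.authors),
                    str(rec.has_full_text).lower(),
                ]
            )
    written = set()
    for rec in corpus.records:
        if not rec.has_full_text or rec.doc_id in written:
            continue
        written.add(rec.doc_id)
        doc = {
            "doc_id": rec.doc_id,
            "body_text": [{"section": s, "text": t} for s, t in rec.body],
        }
        with open(fulltext_dir / f"{rec.doc_id}.json", "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    with open(outdir / "truth.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["doc_id", "topic", "has_fd", "keep"])
        for doc_id, keep in corpus.truth_keep.items():
            writer.writerow(
                [
                    doc_id,
                    corpus.truth_topic.get(doc_id, ""),
                    str(corpus.truth_has_fd[doc_id]).lower(),
                    str(keep).lower(),
                ]
            )
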