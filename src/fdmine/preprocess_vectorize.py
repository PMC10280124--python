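"""Text normalization and TF-IDF vectorization of extracted units.

Normalization removes punctuation, lowercases, filters a standard English
stop-word list (scikit-learn's) plus corpus-specific custom stop words
("paper", "study", "research", "future", "plan" — boilerplate of
future-directions prose), and optionally maps tokens through a pluggable
lemmatizer hook (identity by default, so the pipeline is hermetic; a
biomedical lemmatizer can be slotted in for real corpora).

Vectorization caps the vocabulary at the 5,000 terms with the highest
document frequency (ties broken lexicographically) and weights them with
raw term frequency times smoothed inverse document frequency,
``idf(t) = ln((1+N)/(1+df(t))) + 1``, with L2-normalized rows — the standard
smoothed TF-IDF variant.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS, TfidfTransformer

from .errors import VectorizationError

#: Corpus-specific stop words: generic future-directions boilerplate.
DEFAULT_CUSTOM_STOP_WORDS = frozenset({"paper", "study", "research", "future", "plan"})

#: Standard English stop-word list.
DEFAULT_STOP_WORDS = frozenset(ENGLISH_STOP_WORDS)

# Underscore is kept as a word character (synthetic vocabularies use it);
# every other punctuation mark is deleted, so "COVID-19" and "covid19"
# normalize identically.
_PUNCT_TABLE = str.maketrans("", "", string.punctuation.replace("_", ""))


@dataclass
class TokenizedDoc:
    doc_id: str
    tokens: list[str]


@dataclass
class DocTermMatrix:
    """Documents x terms weight matrix with its vocabulary.

    ``weights`` is a scipy CSR matrix; row order matches ``doc_ids`` and
    column order matches ``vocabulary``.
    """

    doc_ids: list[str]
    vocabulary: list[str]
    weights: sp.csr_matrix

    def toarray(self) -> np.ndarray:
        return np.asarray(self.weights.todense(), dtype=float)


def normalize_text(
    text: str,
    stop_words: Optional[frozenset] = None,
    custom_stop_words: Iterable[str] = DEFAULT_CUSTOM_STOP_WORDS,
    lemmatizer: Optional[Callable[[str], str]] = None,
    doc_id: str = "",
) -> TokenizedDoc:
    """Lowercase, strip punctuation, drop stop words, apply the lemmatizer.

    An empty token list is a legal outcome (a document of only stop words).
    """
    if stop_words is None:
        stop_words = DEFAULT_STOP_WORDS
    stops = set(stop_words) | set(custom_stop_words)
    tokens = []
    for raw in text.lower().translate(_PUNCT_TABLE).split():
        if not raw or raw in stops:
            continue
        if lemmatizer is not None:
            raw = lemmatizer(raw)
            if not raw or raw in stops:
                continue
        tokens.append(raw)
    return TokenizedDoc(doc_id=doc_id, tokens=tokens)


def tokenize_units(
    units,
    stop_words: Optional[frozenset] = None,
    custom_stop_words: Iterable[str] = DEFAULT_CUSTOM_STOP_WORDS,
    lemmatizer: Optional[Callable[[str], str]] = None,
) -> list[TokenizedDoc]:
    """Normalize a list of extracted future-directions units."""
    return [
        normalize_text(u.text, stop_words, custom_stop_words, lemmatizer, doc_id=u.doc_id)
        for u in units
    ]


def select_vocabulary(docs: Sequence[TokenizedDoc], max_features: int) -> list[str]:
    """Top ``max_features`` terms by document frequency, ties lexicographic.

    Document-frequency selection (rather than collection frequency) is stable
    under document-length variation; the returned vocabulary is sorted
    lexicographically for reproducible column order.
    """
    df_counts: Counter = Counter()
    for doc in docs:
        df_counts.update(set(doc.tokens))
    ranked = sorted(df_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return sorted(term for term, _ in ranked[:max_features])


def build_tfidf(docs: Sequence[TokenizedDoc], max_features: int = 5000) -> DocTermMatrix:
    """Build the TF-IDF document-term matrix.

    Rows are L2-normalized unless all-zero (documents with no in-vocabulary
    token keep a zero row).  Raises :class:`VectorizationError` when every
    document is empty.
    """
    if len(docs) < 2:
        raise VectorizationError("need at least two documents to vectorize")
    if all(len(d.tokens) == 0 for d in docs):
        raise VectorizationError("all documents are empty after normalization")
    vocabulary = select_vocabulary(docs, max_features)
    index = {t: j for j, t in enumerate(vocabulary)}
    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        counts = Counter(doc.tokens)
        for term, c in counts.items():
            j = index.get(term)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(c)
    counts_mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), len(vocabulary)), dtype=np.float64
    )
    transformer = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False)
    weights = transformer.fit_transform(counts_mat)
    return DocTermMatrix(
        doc_ids=[d.doc_id for d in docs],
        vocabulary=vocabulary,
        weights=weights.tocsr(),
    )


def term_frequencies(docs: Sequence[TokenizedDoc], top_n: int) -> pd.DataFrame:
    """Exact corpus counts of the ``top_n`` most frequent terms (the tabular
    stand-in for a word-cloud figure); ties broken lexicographically."""
    if not docs:
        raise ValueError("docs must be non-empty")
    counts: Counter = Counter()
    for doc in docs:
        counts.update(doc.tokens)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return pd.DataFrame(ranked, columns=["term", "count"])


def save_matrix(matrix: DocTermMatrix, outdir) -> None:
    """Persist as Matrix Market plus sidecar vocabulary / doc-id text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), matrix.weights)
    (outdir / "vocabulary.txt").write_text("\n".join(matrix.vocabulary) + "\n")
    (outdir / "doc_ids.txt").write_text("\n".join(matrix.doc_ids) + "\n")


def load_matrix(indir) -> DocTermMatrix:
    indir = Path(indir)
    weights = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
    vocabulary = (indir / "vocabulary.txt").read_text().splitlines()
    doc_ids = (indir / "doc_ids.txt").read_text().splitlines()
    return DocTermMatrix(doc_ids=doc_ids, vocabulary=vocabulary, weights=weights)
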