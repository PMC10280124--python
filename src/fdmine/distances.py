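"""The four distance measures used to compare document vectors.

cosine       1 - x.y / (||x|| ||y||)                       range [0, 1] for
                                                           non-negative input
correlation  1 - Pearson(x, y)                             range [0, 2]
jaccard      mismatching positions / union support,        range [0, 1]
             on binarized vectors (entry != 0)
braycurtis   sum|x_k - y_k| / (sum x_k + sum y_k),         range [0, 1] for
             non-negative input

The formulas are dimension-agnostic; the pipeline applies them to document
rows of the TF-IDF or embedding matrix (and they work equally on term
columns).  Degenerate inputs — zero vectors for cosine, constant vectors for
correlation, empty union support for Jaccard, zero total mass for Bray-Curtis
— raise :class:`DegenerateInputError` rather than propagating NaN; the
pairwise driver excludes such rows and reports them instead of aborting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError

METRICS = ("cosine", "correlation", "jaccard", "braycurtis")


@dataclass
class PairwiseDistances:
    ids: list[str]
    metric: str
    values: np.ndarray  # symmetric, zero diagonal
    excluded: list[int] = field(default_factory=list)  # degenerate row indices


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def _degenerate_reason(v: np.ndarray, metric: str) -> str | None:
    if metric == "cosine" and not np.any(v):
        return "zero vector"
    if metric == "correlation" and np.ptp(v) == 0:
        return "constant vector"
    return None


def distance(x, y, metric: str) -> float:
    """Distance between two equal-length vectors under ``metric``."""
    _check_metric(metric)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be 1-D vectors of equal length >= 1")

    if metric == "cosine":
        for name, v in (("x", x), ("y", y)):
            if _degenerate_reason(v, metric):
                raise DegenerateInputError(f"cosine distance undefined for zero vector {name}")
        sim = float(x @ y) / (np.linalg.norm(x) * np.linalg.norm(y))
        return float(min(2.0, max(0.0, 1.0 - sim)))

    if metric == "correlation":
        for name, v in (("x", x), ("y", y)):
            if _degenerate_reason(v, metric):
                raise DegenerateInputError(
                    f"correlation distance undefined for constant vector {name}"
                )
        xc, yc = x - x.mean(), y - y.mean()
        r = float(xc @ yc) / (np.linalg.norm(xc) * np.linalg.norm(yc))
        return float(min(2.0, max(0.0, 1.0 - r)))

    if metric == "jaccard":
        xs, ys = x != 0, y != 0
        union = xs | ys
        if not union.any():
            raise DegenerateInputError("jaccard distance undefined for two all-zero vectors")
        return float(np.count_nonzero(xs != ys) / np.count_nonzero(union))

    # braycurtis; defined for non-negative inputs
    denom = float(x.sum() + y.sum())
    if denom == 0.0:
        raise DegenerateInputError("braycurtis distance undefined for zero total mass")
    return float(np.abs(x - y).sum() / denom)


def _as_dense(rows) -> np.ndarray:
    if hasattr(rows, "toarray"):
        rows = rows.toarray()
    return np.asarray(rows, dtype=float)


def cross_distances(a, b, metric: str) -> np.ndarray:
    """Vectorized (len(a) x len(b)) distance matrix; rows must satisfy the
    metric's preconditions."""
    _check_metric(metric)
    A, B = _as_dense(a), _as_dense(b)
    if metric in ("cosine", "correlation"):
        if metric == "correlation":
            A = A - A.mean(axis=1, keepdims=True)
            B = B - B.mean(axis=1, keepdims=True)
        na = np.linalg.norm(A, axis=1)
        nb = np.linalg.norm(B, axis=1)
        if np.any(na == 0) or np.any(nb == 0):
            raise DegenerateInputError(f"{metric}: degenerate row in input")
        sim = (A / na[:, None]) @ (B / nb[:, None]).T
        return np.clip(1.0 - sim, 0.0, 2.0)
    if metric == "jaccard":
        Ab = (A != 0).astype(float)
        Bb = (B != 0).astype(float)
        inter = Ab @ Bb.T
        union = Ab.sum(axis=1)[:, None] + Bb.sum(axis=1)[None, :] - inter
        if np.any(union == 0):
            raise DegenerateInputError("jaccard: pair of all-zero rows")
        return (union - inter) / union
    # braycurtis
    sums = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :]
    if np.any(sums == 0):
        raise DegenerateInputError("braycurtis: pair with zero total mass")
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        out[i] = np.abs(B - A[i]).sum(axis=1)
    return out / sums


def pairwise(rows, metric: str, ids=None) -> PairwiseDistances:
    """Symmetric pairwise distance matrix over matrix rows.

    Rows that violate the metric's preconditions are excluded (their entries
    set to 0) and listed in ``excluded`` rather than aborting the whole
    matrix; downstream policy decides how to treat them.
    """
    _check_metric(metric)
    X = _as_dense(rows)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    n = X.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]

    excluded = []
    for i in range(n):
        if metric in ("cosine", "braycurtis", "jaccard") and not np.any(X[i]):
            excluded.append(i)
        elif metric == "correlation" and np.ptp(X[i]) == 0:
            excluded.append(i)
    ok = np.array([i for i in range(n) if i not in set(excluded)], dtype=int)

    values = np.zeros((n, n))
    if ok.size >= 1:
        sub = cross_distances(X[ok], X[ok], metric)
        values[np.ix_(ok, ok)] = sub
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return PairwiseDistances(ids=list(ids), metric=metric, values=values, excluded=excluded)
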