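"""Clustering of document embeddings and its evaluation.

Clustering is generalized Lloyd iteration (k-means with a pluggable
assignment distance): points are assigned to the nearest center under the
chosen metric (ties to the lowest cluster index), centers are recomputed as
the coordinate mean of their members (re-normalized for cosine), and the best
of several seeded restarts by total within-cluster distance is returned.

Evaluation uses the plug-in information-theoretic quantities (natural log,
0 log 0 = 0):

    H(X)     = -sum_i p(x_i) ln p(x_i)
    I(X;Y)   = sum_xy p(x,y) ln [ p(x,y) / (p(x) p(y)) ]
    NMI(X;Y) = 2 I(X;Y) / (H(X) + H(Y))

and the elbow method: distortion — the total squared Euclidean distance of
each sample to its cluster's coordinate-mean centroid — scanned over
k in [2, 20], with the knee selected as the k maximizing the discrete second
difference of the distortion curve (a manual override replaces the visual
auxiliary-line judgment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .autoencoder import (
    AutoencoderConfig,
    EmbeddingMatrix,
    encode,
    train_autoencoder,
)
from .distances import METRICS, cross_distances
from .errors import DegenerateInputError


@dataclass
class ClusterAssignment:
    doc_ids: list[str]
    labels: np.ndarray  # integers in [0, k)
    k: int
    metric: str
    centers: np.ndarray  # k x dim
    seed: int


@dataclass
class ElbowCurve:
    k_values: list[int]
    distortions: list[float]
    knee: Optional[int]
    reliable: bool
    strength: float  # curvature at the knee as a fraction of the total drop


def _as_matrix(emb) -> tuple[list[str], np.ndarray]:
    if hasattr(emb, "vectors"):  # EmbeddingMatrix or duck-typed equivalent
        return list(emb.doc_ids), np.asarray(emb.vectors, dtype=float)
    if hasattr(emb, "weights"):  # DocTermMatrix
        return list(emb.doc_ids), emb.toarray()
    X = np.asarray(emb, dtype=float)
    return [str(i) for i in range(X.shape[0])], X


def _update_centers(X, labels, k, metric, centers_old):
    centers = centers_old.copy()
    for c in range(k):
        members = X[labels == c]
        if len(members) == 0:
            continue
        mean = members.mean(axis=0)
        if metric == "cosine":
            norm = np.linalg.norm(mean)
            if norm > 0:
                mean = mean / norm
            else:
                mean = centers_old[c]
        centers[c] = mean
    return centers


def _plusplus_init(X, k, metric, rng) -> np.ndarray:
    """D^2-style seeding under the assignment metric: the first center is
    uniform, each further center is drawn with probability proportional to
    the squared distance to the nearest chosen center."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = cross_distances(X, centers[:1], metric)[:, 0] ** 2
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[c] = X[rng.integers(n)]
        else:
            centers[c] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, cross_distances(X, centers[c : c + 1], metric)[:, 0] ** 2)
    return centers


def cluster_embeddings(
    emb,
    k: int,
    metric: str = "cosine",
    seed: int = 0,
    max_iter: int = 100,
    restarts: int = 5,
) -> ClusterAssignment:
    """Lloyd-style clustering of embedding rows under ``metric``.

    Deterministic for a fixed seed; empty clusters are reseeded from the point
    farthest from its current center; the best of ``restarts`` runs by total
    within-cluster distance wins.  ``k = 1`` trivially assigns every point to
    cluster 0.
    """
    doc_ids, X = _as_matrix(emb)
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "cosine" and np.any(~X.any(axis=1)):
        raise DegenerateInputError("cosine clustering requires non-zero rows")
    if metric == "correlation" and np.any(np.ptp(X, axis=1) == 0):
        raise DegenerateInputError("correlation clustering requires non-constant rows")

    if k == 1:
        labels = np.zeros(n, dtype=int)
        centers = _update_centers(X, labels, 1, metric, X[:1].copy())
        return ClusterAssignment(doc_ids, labels, 1, metric, centers, seed)

    rng = np.random.default_rng(seed)
    best: Optional[tuple[float, np.ndarray, np.ndarray]] = None
    for _ in range(max(1, restarts)):
        centers = _plusplus_init(X, k, metric, rng)
        labels = np.full(n, -1, dtype=int)
        for _ in range(max_iter):
            D = cross_distances(X, centers, metric)
            new_labels = np.argmin(D, axis=1)  # argmin takes the lowest index on ties
            # reseed empty clusters from the farthest point
            for c in range(k):
                if not np.any(new_labels == c):
                    far = int(np.argmax(D[np.arange(n), new_labels]))
                    new_labels[far] = c
                    centers[c] = X[far]
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centers = _update_centers(X, labels, k, metric, centers)
        D = cross_distances(X, centers, metric)
        objective = float(D[np.arange(n), labels].sum())
        if best is None or objective < best[0]:
            best = (objective, labels.copy(), centers.copy())
    _, labels, centers = best
    return ClusterAssignment(doc_ids, labels, k, metric, centers, seed)


def distortion(emb, assignment: ClusterAssignment) -> float:
    """Total squared Euclidean distance of each point to its cluster's
    coordinate-mean centroid, regardless of the assignment metric."""
    _, X = _as_matrix(emb)
    total = 0.0
    for c in range(assignment.k):
        members = X[assignment.labels == c]
        if len(members) == 0:
            continue
        centroid = members.mean(axis=0)
        total += float(((members - centroid) ** 2).sum())
    return total


def elbow_scan(
    emb,
    k_range: tuple[int, int] = (2, 20),
    metric: str = "cosine",
    seed: int = 0,
    restarts: int = 5,
    knee_override: Optional[int] = None,
    reliability_min: float = 0.3,
) -> ElbowCurve:
    """Distortion curve over ``k_range`` with knee selection.

    The knee is the interior k maximizing the discrete second difference
    ``d[k-1] - 2 d[k] + d[k+1]``; its strength is that curvature as a fraction
    of the curve's total drop.  A knee with strength below ``reliability_min``
    (or a flat curve) is flagged unreliable: curves from structureless data
    decay smoothly and spread their curvature, whereas planted structure
    concentrates it at the true k.
    """
    _, X = _as_matrix(emb)
    lo, hi = k_range
    hi = min(hi, X.shape[0])
    if lo < 1 or hi < lo:
        raise ValueError("invalid k range")
    ks = list(range(lo, hi + 1))
    distortions = []
    for k in ks:
        assignment = cluster_embeddings(X, k, metric=metric, seed=seed, restarts=restarts)
        distortions.append(distortion(X, assignment))

    if knee_override is not None:
        return ElbowCurve(ks, distortions, knee_override, True, float("nan"))

    # Converged distortion is non-increasing in k; imperfectly converged runs
    # put small upward bumps on the plateau that masquerade as curvature.
    # Knee detection therefore works on the monotone (running-minimum)
    # envelope of the curve; the raw curve is what gets reported.
    d = np.minimum.accumulate(np.asarray(distortions))
    drop = float(d.max() - d.min())
    if len(ks) < 3 or drop <= 0.0:
        return ElbowCurve(ks, distortions, None, False, 0.0)
    second = d[:-2] - 2.0 * d[1:-1] + d[2:]
    j = int(np.argmax(second))
    strength = float(second[j] / drop)
    knee = ks[j + 1]
    return ElbowCurve(ks, distortions, knee, strength >= reliability_min, strength)


# --- information-theoretic evaluation ------------------------------------


def entropy(labels: Sequence) -> float:
    """Plug-in entropy of the empirical label distribution, in nats."""
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(a: Sequence, b: Sequence) -> float:
    """Plug-in mutual information of two labelings, in nats; zero-count cells
    contribute 0."""
    a, b = list(a), list(b)
    if len(a) != len(b) or not a:
        raise ValueError("labelings must be non-empty and of equal length")
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float)
    n = table.sum()
    pxy = table / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = (pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])).sum()
    return float(max(0.0, mi))


def nmi(a: Sequence, b: Sequence) -> float:
    """Normalized mutual information 2 I / (H(a) + H(b)) in [0, 1].

    Convention: two identical single-class labelings (both entropies zero)
    are identical partitions, so NMI = 1.
    """
    ha, hb = entropy(a), entropy(b)
    if ha + hb == 0.0:
        return 1.0
    return float(min(1.0, 2.0 * mutual_information(a, b) / (ha + hb)))


# --- distance-metric comparison harness -----------------------------------


@dataclass
class MetricComparison:
    table: pd.DataFrame  # columns: metric, nmi, final_loss, eval_loss
    loss_history: list[float]
    assignments: dict[str, ClusterAssignment] = field(default_factory=dict)


def compare_metrics(
    matrix,
    config: AutoencoderConfig,
    k: int,
    reference: Sequence,
    seed: int = 0,
    restarts: int = 5,
) -> MetricComparison:
    """Cluster the same embeddings under each of the four metrics and score
    them by NMI against ``reference``.

    The autoencoder objective (MSE) does not depend on the clustering metric,
    so one model is trained per shared seed and reused; ``eval_loss`` reports
    the per-metric mean reconstruction distance (the metric applied to each
    row and its reconstruction) as a metric-specific convergence summary.
    The table is sorted by NMI descending.
    """
    cfg = AutoencoderConfig(**{**config.__dict__, "seed": seed})
    model, history = train_autoencoder(matrix, cfg)
    emb = encode(model, matrix)
    _, X = _as_matrix(matrix)
    X_hat = model.reconstruct(X)
    reference = list(reference)

    rows = []
    assignments = {}
    for metric in METRICS:
        assignment = cluster_embeddings(emb, k, metric=metric, seed=seed, restarts=restarts)
        assignments[metric] = assignment
        score = nmi(assignment.labels.tolist(), reference)
        try:
            per_doc = cross_distances(X, X_hat, metric).diagonal()
            eval_loss = float(per_doc.mean())
        except DegenerateInputError:
            eval_loss = float("nan")
        rows.append({"metric": metric, "nmi": score,
                     "final_loss": history.per_epoch[-1], "eval_loss": eval_loss})
    table = (
        pd.DataFrame(rows)
        .sort_values("nmi", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return MetricComparison(table=table, loss_history=history.per_epoch, assignments=assignments)
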