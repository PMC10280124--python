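"""Cluster keyword profiles, monthly topic timelines, and topic-evolution
classification.

Keywords per cluster are ranked by a contrast score — mean in-cluster TF-IDF
weight minus mean out-of-cluster weight — so terms that are merely globally
frequent do not dominate.

The observation window is split into three contiguous, as-equal-as-possible
stages (prophase / metaphase / telophase: the rising, growth, and degradation
stages of the topic life cycle).  Between adjacent stages each topic receives
exactly one evolution event, drawn from the five-type taxonomy birth /
inheritance / division / merger / extinction: a topic whose stage-mean
proportion rises above the threshold (strict >, default 5%) is born unless it
is fed by a splitting or merging predecessor; one that falls below goes
extinct; topics above threshold in both stages are classified by where their
overlap mass goes — a dominant one-to-one link is inheritance, mass split
over several strong successors is division, and several topics concentrating
on one successor is a merger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clustering_eval import ClusterAssignment, cluster_embeddings
from .distances import cross_distances
from .preprocess_vectorize import DocTermMatrix

STAGES = ("prophase", "metaphase", "telophase")

#: Threshold between birth and extinction on stage-mean proportions (strict >).
DEFAULT_THRESHOLD = 0.05
#: Minimum row/column share of overlap mass for a one-to-one inheritance link.
DEFAULT_INHERIT_MIN = 0.6
#: Minimum row share of overlap mass for a division/merger branch.
DEFAULT_BRANCH_MIN = 0.25


@dataclass
class KeywordProfile:
    """cluster -> ranked (term, contrast weight), weights non-increasing."""

    per_cluster: dict[int, list[tuple[str, float]]]


@dataclass
class TopicTimeline:
    months: list[str]  # "YYYY-MM", ordered
    counts: np.ndarray  # months x k integers
    proportions: np.ndarray  # months x k, rows sum to 1 (0 rows flagged)
    empty_months: list[str] = field(default_factory=list)


@dataclass
class EvolutionEvent:
    event_type: str  # birth | inheritance | division | merger | extinction
    stage: str  # the later stage of the transition where the event lands
    source_topics: list[int]
    target_topics: list[int]
    evidence: dict = field(default_factory=dict)


def cluster_keywords(
    matrix: DocTermMatrix,
    assignment: ClusterAssignment,
    top_n: int = 10,
) -> KeywordProfile:
    """Rank each cluster's terms by mean in-cluster weight minus mean
    out-of-cluster weight."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if list(matrix.doc_ids) != list(assignment.doc_ids):
        raise ValueError("assignment rows do not align with matrix rows")
    X = matrix.toarray()
    labels = np.asarray(assignment.labels)
    profile: dict[int, list[tuple[str, float]]] = {}
    for c in range(assignment.k):
        inside = labels == c
        mean_in = X[inside].mean(axis=0) if inside.any() else np.zeros(X.shape[1])
        outside = ~inside
        mean_out = X[outside].mean(axis=0) if outside.any() else np.zeros(X.shape[1])
        contrast = mean_in - mean_out
        order = np.argsort(-contrast, kind="stable")[:top_n]
        profile[c] = [(matrix.vocabulary[j], float(contrast[j])) for j in order]
    return profile_sorted(KeywordProfile(per_cluster=profile))


def profile_sorted(profile: KeywordProfile) -> KeywordProfile:
    for c, ranked in profile.per_cluster.items():
        profile.per_cluster[c] = sorted(ranked, key=lambda tw: -tw[1])
    return profile


def monthly_proportions(
    assignment: ClusterAssignment,
    dates: Mapping[str, str],
    months: Optional[Sequence[str]] = None,
) -> TopicTimeline:
    """Per-month, per-cluster document counts and proportions.

    ``dates`` maps doc_id to a "YYYY-MM" stamp.  When ``months`` is given it
    defines the observation window and a document outside it is an error;
    otherwise the window spans the observed months.  Months with zero
    documents are flagged, and their proportion rows left at zero rather than
    fabricated.
    """
    stamps = {}
    for doc_id in assignment.doc_ids:
        if doc_id not in dates:
            raise ValueError(f"no date for document {doc_id}")
        stamps[doc_id] = str(dates[doc_id])[:7]
    if months is None:
        months = sorted(set(stamps.values()))
    months = list(months)
    month_index = {m: i for i, m in enumerate(months)}
    for doc_id, stamp in stamps.items():
        if stamp not in month_index:
            raise ValueError(f"document {doc_id} dated {stamp} outside the window {months}")

    counts = np.zeros((len(months), assignment.k), dtype=int)
    for doc_id, label in zip(assignment.doc_ids, assignment.labels):
        counts[month_index[stamps[doc_id]], int(label)] += 1
    totals = counts.sum(axis=1)
    proportions = np.zeros_like(counts, dtype=float)
    nonzero = totals > 0
    proportions[nonzero] = counts[nonzero] / totals[nonzero, None]
    empty = [m for m, t in zip(months, totals) if t == 0]
    return TopicTimeline(months=months, counts=counts, proportions=proportions,
                         empty_months=empty)


def stage_partition(months: Sequence[str]) -> dict[str, str]:
    """Split the ordered month list into three contiguous blocks, as equal as
    possible (remainder to the earlier blocks), mapped to
    prophase/metaphase/telophase in order."""
    months = list(months)
    n = len(months)
    if n < 3:
        raise ValueError("need at least three months to define three stages")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    mapping: dict[str, str] = {}
    pos = 0
    for stage, size in zip(STAGES, sizes):
        for m in months[pos : pos + size]:
            mapping[m] = stage
        pos += size
    return mapping


def stage_mean_proportions(timeline: TopicTimeline, stages: Mapping[str, str]) -> np.ndarray:
    """Document-weighted mean proportion per (stage, topic): total stage
    counts normalized within each stage.  Returns a 3 x k array."""
    k = timeline.counts.shape[1]
    out = np.zeros((3, k))
    for s_idx, stage in enumerate(STAGES):
        rows = [i for i, m in enumerate(timeline.months) if stages.get(m) == stage]
        stage_counts = timeline.counts[rows].sum(axis=0)
        total = stage_counts.sum()
        if total > 0:
            out[s_idx] = stage_counts / total
    return out


def stage_overlaps(
    emb,
    assignment: ClusterAssignment,
    dates: Mapping[str, str],
    stages: Mapping[str, str],
    metric: str = "cosine",
) -> list[np.ndarray]:
    """Row-normalized document-flow overlap matrices between adjacent stages.

    For each stage the centroid of every cluster is recomputed from that
    stage's documents only.  ``overlap[i, j]`` between stage t and t+1 is the
    fraction of cluster i's stage-t documents whose nearest stage-(t+1)
    centroid (under ``metric``) is cluster j — i.e. where cluster i's content
    goes.  A stable topic yields a near-identity row; content drifting toward
    several successors spreads its row mass.  Rows of clusters absent from a
    stage are left all-zero.
    """
    from .clustering_eval import _as_matrix

    doc_ids, X = _as_matrix(emb)
    labels = np.asarray(assignment.labels)
    doc_stage = np.array([stages[str(dates[d])[:7]] for d in doc_ids])
    k = assignment.k
    centroids = []
    for stage in STAGES:
        mask_stage = doc_stage == stage
        C = np.zeros((k, X.shape[1]))
        for c in range(k):
            members = X[mask_stage & (labels == c)]
            if len(members) > 0:
                C[c] = members.mean(axis=0)
        centroids.append(C)

    matrices = []
    for t in range(2):
        B = centroids[t + 1]
        present = np.array([B[c].any() for c in range(k)])
        overlap = np.zeros((k, k))
        mask_stage = doc_stage == STAGES[t]
        if present.any() and mask_stage.any():
            D = cross_distances(X[mask_stage], B[present], metric)
            nearest = np.flatnonzero(present)[np.argmin(D, axis=1)]
            for i, j in zip(labels[mask_stage], nearest):
                overlap[i, j] += 1
        sums = overlap.sum(axis=1, keepdims=True)
        np.divide(overlap, sums, out=overlap, where=sums > 0)
        matrices.append(overlap)
    return matrices


def _check_overlap(overlap: np.ndarray, k: int) -> None:
    overlap = np.asarray(overlap, dtype=float)
    if overlap.shape != (k, k):
        raise ValueError(f"overlap matrix must be {k}x{k}")
    if np.any(overlap < -1e-12) or np.any(overlap > 1 + 1e-12):
        raise ValueError("overlap entries must lie in [0, 1]")
    sums = overlap.sum(axis=1)
    bad = ~(np.isclose(sums, 1.0, atol=1e-6) | np.isclose(sums, 0.0, atol=1e-12))
    if np.any(bad):
        raise ValueError("overlap rows must be normalized to sum to 1 (or be all-zero)")


def classify_evolution(
    timeline: TopicTimeline,
    stage_overlap: Sequence[np.ndarray],
    threshold: float = DEFAULT_THRESHOLD,
    inherit_min: float = DEFAULT_INHERIT_MIN,
    branch_min: float = DEFAULT_BRANCH_MIN,
    stages: Optional[Mapping[str, str]] = None,
) -> list[EvolutionEvent]:
    """Classify every topic's transition between adjacent stages.

    Deterministic in its inputs.  Stage-mean proportions (document-weighted)
    are compared against ``threshold`` with a strict ``>``: a boundary value
    of exactly the threshold is not above it.  Survivor topics (above
    threshold in both stages) are classified by their row of the
    row-normalized overlap matrix: >= 2 branches of at least ``branch_min``
    is a division; a single dominant link holding at least ``inherit_min`` of
    both its row and its column mass is an inheritance; dominant links that
    share their successor form a merger (a lone merger candidate falls back
    to inheritance).
    """
    if stages is None:
        stages = stage_partition(timeline.months)
    k = timeline.counts.shape[1]
    if len(stage_overlap) != 2:
        raise ValueError("need one overlap matrix per adjacent stage pair")
    for overlap in stage_overlap:
        _check_overlap(np.asarray(overlap, dtype=float), k)
    means = stage_mean_proportions(timeline, stages)

    events: list[EvolutionEvent] = []
    for t in range(2):
        later_stage = STAGES[t + 1]
        overlap = np.asarray(stage_overlap[t], dtype=float)
        above0 = means[t] > threshold
        above1 = means[t + 1] > threshold
        survivors = [i for i in range(k) if above0[i] and above1[i]]
        survivor_set = set(survivors)
        # column mass restricted to survivor rows
        col_mass = overlap[survivors].sum(axis=0) if survivors else np.zeros(k)

        merger_candidates: dict[int, list[int]] = {}
        strong_targets_of: dict[int, list[int]] = {}
        for i in survivors:
            strong = [j for j in range(k) if above1[j] and overlap[i, j] >= branch_min]
            strong_targets_of[i] = strong
            if len(strong) >= 2:
                events.append(
                    EvolutionEvent(
                        "division",
                        later_stage,
                        [i],
                        sorted(strong),
                        {"branches": {int(j): float(overlap[i, j]) for j in strong}},
                    )
                )
                continue
            j = int(np.argmax(overlap[i])) if overlap[i].any() else i
            row_share = float(overlap[i, j])
            col_share = row_share / col_mass[j] if col_mass[j] > 0 else 1.0
            if row_share >= inherit_min and col_share >= inherit_min:
                events.append(
                    EvolutionEvent(
                        "inheritance",
                        later_stage,
                        [i],
                        [j],
                        {"row_share": row_share, "col_share": col_share},
                    )
                )
            else:
                merger_candidates.setdefault(j, []).append(i)

        for j, sources in sorted(merger_candidates.items()):
            if len(sources) >= 2:
                events.append(
                    EvolutionEvent(
                        "merger",
                        later_stage,
                        sorted(sources),
                        [j],
                        {"row_shares": {int(i): float(overlap[i, j]) for i in sources}},
                    )
                )
            else:
                i = sources[0]
                events.append(
                    EvolutionEvent(
                        "inheritance",
                        later_stage,
                        [i],
                        [j],
                        {"row_share": float(overlap[i, j]), "fallback": True},
                    )
                )

        # topics fed >= branch_min by a splitting/merging survivor are
        # division/merger targets, not births
        fed = set()
        for i in survivors:
            for j in strong_targets_of[i]:
                fed.add(j)
        for j in range(k):
            if above1[j] and not above0[j] and j not in fed:
                events.append(
                    EvolutionEvent(
                        "birth",
                        later_stage,
                        [],
                        [j],
                        {"from": float(means[t, j]), "to": float(means[t + 1, j])},
                    )
                )
        for i in range(k):
            if above0[i] and not above1[i]:
                events.append(
                    EvolutionEvent(
                        "extinction",
                        later_stage,
                        [i],
                        [],
                        {"from": float(means[t, i]), "to": float(means[t + 1, i])},
                    )
                )
    return events


def per_stage_clustering(
    emb,
    dates: Mapping[str, str],
    stages: Mapping[str, str],
    k: int,
    metric: str = "cosine",
    seed: int = 0,
):
    """Cluster each stage's documents independently (same k policy); returns
    stage -> ClusterAssignment for overlap analyses that do not assume a
    global clustering."""
    from .clustering_eval import _as_matrix

    doc_ids, X = _as_matrix(emb)
    doc_stage = np.array([stages[str(dates[d])[:7]] for d in doc_ids])
    out = {}
    for stage in STAGES:
        mask = doc_stage == stage
        ids = [d for d, m in zip(doc_ids, mask) if m]
        if mask.sum() < k:
            raise ValueError(f"stage {stage} has fewer documents than k={k}")
        out[stage] = cluster_embeddings(
            EmbeddingMatrixLike(ids, X[mask]), k, metric=metric, seed=seed
        )
    return out


@dataclass
class EmbeddingMatrixLike:
    doc_ids: list[str]
    vectors: np.ndarray


def timeline_frame(timeline: TopicTimeline) -> pd.DataFrame:
    """Long-form month,cluster,count,proportion table for export."""
    rows = []
    k = timeline.counts.shape[1]
    for i, month in enumerate(timeline.months):
        for c in range(k):
            rows.append(
                {
                    "month": month,
                    "cluster": c,
                    "count": int(timeline.counts[i, c]),
                    "proportion": float(timeline.proportions[i, c]),
                }
            )
    return pd.DataFrame(rows)
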