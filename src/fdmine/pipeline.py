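"""Configured, logged, resumable pipeline wiring all stages together.

Every stage reads its inputs from and writes its outputs to the run
directory, so invoking the stages one at a time (via the CLI) produces
byte-identical artifacts to the end-to-end ``run_pipeline``.  One global seed
fans out to per-stage seeds through a fixed stage-name hash, making each
stage independently reproducible.

Artifacts (all plain text): cleaning audit CSV, extracted-units CSV, Matrix
Market TF-IDF matrix with sidecars, per-epoch loss CSV, embeddings TSV,
elbow curve CSV, assignment CSV, keyword CSV, timeline CSV, evolution events
JSON, and a manifest listing every output with a checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autoencoder import (
    AutoencoderConfig,
    AutoencoderModel,
    EmbeddingMatrix,
    encode,
    save_embeddings,
    train_autoencoder,
)
from .clustering_eval import ClusterAssignment, cluster_embeddings, elbow_scan, nmi
from .errors import ConfigurationError
from .ingest_extract import (
    DEFAULT_KEYWORDS,
    clean_corpus,
    evaluate_extraction,
    extract_corpus,
    load_corpus,
)
from .preprocess_vectorize import (
    DocTermMatrix,
    build_tfidf,
    load_matrix,
    save_matrix,
    term_frequencies,
    tokenize_units,
    DEFAULT_CUSTOM_STOP_WORDS,
)
from .topic_analysis import (
    classify_evolution,
    cluster_keywords,
    monthly_proportions,
    stage_overlaps,
    stage_partition,
    timeline_frame,
)

logger = logging.getLogger("fdmine")


@dataclass
class PipelineConfig:
    """Pipeline settings; the defaults reproduce the reference analysis
    conditions (5,000 TF-IDF features, learning rate 1e-4, batch size 7,
    betas 0.9/0.999, cosine metric, elbow range [2, 20], 5% evolution
    threshold)."""

    metadata_path: str = "metadata.csv"
    fulltext_dir: str = "fulltext"
    output_dir: str = "out"
    truth_path: Optional[str] = None  # synthetic truth table, if available
    keywords: Sequence[str] = DEFAULT_KEYWORDS
    custom_stop_words: Sequence[str] = tuple(sorted(DEFAULT_CUSTOM_STOP_WORDS))
    max_features: int = 5000
    hidden_dims: Sequence[int] = (1024, 512, 128, 64)
    bottleneck_dim: int = 32
    learning_rate: float = 0.0001
    batch_size: int = 7
    steps_per_epoch: int = 300
    epochs: int = 100
    metric: str = "cosine"
    k: object = "elbow"  # fixed integer or the string "elbow"
    k_range: tuple[int, int] = (2, 20)
    restarts: int = 5
    evolution_threshold: float = 0.05
    inherit_min: float = 0.6
    branch_min: float = 0.25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.k, str) and cfg.k != "elbow":
            raise ConfigurationError("k must be an integer or 'elbow'")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["keywords"] = list(self.keywords)
        d["custom_stop_words"] = list(self.custom_stop_words)
        d["hidden_dims"] = list(self.hidden_dims)
        d["k_range"] = list(self.k_range)
        return d

    def autoencoder_config(self, input_dim: int) -> AutoencoderConfig:
        return AutoencoderConfig(
            input_dim=input_dim,
            hidden_dims=tuple(self.hidden_dims),
            bottleneck_dim=self.bottleneck_dim,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            steps_per_epoch=self.steps_per_epoch,
            epochs=self.epochs,
            seed=derive_seed(self.seed, "train"),
        )


def derive_seed(global_seed: int, stage: str) -> int:
    """Fan one global seed out to per-stage seeds via a fixed stage-name
    hash; results stay below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _log(stage: str, **counts) -> None:
    logger.info(json.dumps({"stage": stage, **counts}, sort_keys=True))


def _out(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# --- stages ----------------------------------------------------------------


def stage_ingest(config: PipelineConfig) -> list:
    records = load_corpus(config.metadata_path, config.fulltext_dir, dedup="none")
    _log("ingest", loaded=len(records))
    return records


def stage_clean(config: PipelineConfig):
    records = stage_ingest(config)
    kept, audit = clean_corpus(records)
    out = _out(config)
    audit.to_csv(out / "cleaning_audit.csv", index=False)
    rows = [
        {"doc_id": r.doc_id, "month": r.publish_date.strftime("%Y-%m")}
        for r in kept
    ]
    pd.DataFrame(rows, columns=["doc_id", "month"]).to_csv(out / "kept.csv", index=False)
    reason_counts = audit["reason"].value_counts().to_dict() if len(audit) else {}
    _log("clean", kept=len(kept), dropped=len(audit), **reason_counts)
    return kept, audit


def stage_extract(config: PipelineConfig):
    kept, _ = stage_clean(config)
    units = extract_corpus(kept, config.keywords)
    out = _out(config)
    pd.DataFrame(
        [
            {
                "doc_id": u.doc_id,
                "matched_rule": u.matched_rule,
                "matched_keywords": ";".join(u.matched_keywords),
                "text": u.text,
            }
            for u in units
        ],
        columns=["doc_id", "matched_rule", "matched_keywords", "text"],
    ).to_csv(out / "fd_units.csv", index=False)
    _log("extract", candidates=len(kept), extracted=len(units))
    return units


def stage_vectorize(config: PipelineConfig) -> DocTermMatrix:
    out = _out(config)
    units_df = pd.read_csv(out / "fd_units.csv", dtype=str, keep_default_na=False)
    units = [
        type("Unit", (), {"doc_id": r.doc_id, "text": r.text})
        for r in units_df.itertuples(index=False)
    ]
    docs = tokenize_units(units, custom_stop_words=set(config.custom_stop_words))
    matrix = build_tfidf(docs, max_features=config.max_features)
    save_matrix(matrix, out / "tfidf")
    term_frequencies(docs, top_n=50).to_csv(out / "term_frequencies.csv", index=False)
    _log("vectorize", documents=len(matrix.doc_ids), features=len(matrix.vocabulary))
    return matrix


def stage_train(config: PipelineConfig) -> EmbeddingMatrix:
    out = _out(config)
    matrix = load_matrix(out / "tfidf")
    ae_config = config.autoencoder_config(input_dim=len(matrix.vocabulary))
    model, history = train_autoencoder(matrix, ae_config)
    model.save(out / "model")
    pd.DataFrame(
        {"epoch": range(len(history.per_epoch)), "loss": history.per_epoch}
    ).to_csv(out / "loss_history.csv", index=False)
    emb = encode(model, matrix)
    save_embeddings(emb, out / "embeddings.tsv")
    _log("train", epochs=len(history.per_epoch), final_loss=history.per_epoch[-1])
    return emb


def load_embeddings(path) -> EmbeddingMatrix:
    ids, rows = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split("\t")
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return EmbeddingMatrix(doc_ids=ids, vectors=np.asarray(rows))


def stage_elbow(config: PipelineConfig) -> int:
    out = _out(config)
    emb = load_embeddings(out / "embeddings.tsv")
    curve = elbow_scan(
        emb,
        k_range=tuple(config.k_range),
        metric=config.metric,
        seed=derive_seed(config.seed, "cluster"),
        restarts=config.restarts,
    )
    pd.DataFrame({"k": curve.k_values, "distortion": curve.distortions}).to_csv(
        out / "elbow.csv", index=False
    )
    (out / "selected_k.json").write_text(
        json.dumps(
            {"k": curve.knee, "reliable": curve.reliable, "strength": curve.strength}
        )
    )
    _log("elbow", selected_k=curve.knee, reliable=curve.reliable)
    if curve.knee is None:
        raise RuntimeError("elbow scan found no knee; set a fixed k")
    return curve.knee


def _resolve_k(config: PipelineConfig, out: Path) -> int:
    if config.k == "elbow":
        selected = out / "selected_k.json"
        if not selected.exists():
            return stage_elbow(config)
        return int(json.loads(selected.read_text())["k"])
    return int(config.k)


def stage_cluster(config: PipelineConfig) -> ClusterAssignment:
    out = _out(config)
    emb = load_embeddings(out / "embeddings.tsv")
    k = _resolve_k(config, out)
    assignment = cluster_embeddings(
        emb,
        k,
        metric=config.metric,
        seed=derive_seed(config.seed, "cluster"),
        restarts=config.restarts,
    )
    pd.DataFrame({"doc_id": assignment.doc_ids, "label": assignment.labels}).to_csv(
        out / "assignment.csv", index=False
    )
    matrix = load_matrix(out / "tfidf")
    profile = cluster_keywords(matrix, assignment, top_n=10)
    rows = []
    for c, ranked in sorted(profile.per_cluster.items()):
        for rank, (term, weight) in enumerate(ranked, start=1):
            rows.append({"cluster": c, "rank": rank, "term": term, "weight": weight})
    pd.DataFrame(rows).to_csv(out / "keywords.csv", index=False)
    _log("cluster", k=k, metric=config.metric)
    return assignment


def _read_assignment(out: Path) -> ClusterAssignment:
    df = pd.read_csv(out / "assignment.csv", dtype={"doc_id": str, "label": int})
    labels = df["label"].to_numpy()
    k = int(labels.max()) + 1
    return ClusterAssignment(
        doc_ids=df["doc_id"].tolist(),
        labels=labels,
        k=k,
        metric="cosine",
        centers=np.zeros((k, 1)),
        seed=0,
    )


def stage_evaluate(config: PipelineConfig) -> dict:
    out = _out(config)
    result: dict = {}
    assignment = _read_assignment(out)
    if config.truth_path:
        truth = pd.read_csv(config.truth_path, dtype=str, keep_default_na=False)
        truth_topic = {
            r.doc_id: int(r.topic) for r in truth.itertuples(index=False) if r.topic != ""
        }
        truth_has_fd = {r.doc_id: r.has_fd == "true" for r in truth.itertuples(index=False)}
        labeled = [d for d in assignment.doc_ids if d in truth_topic]
        if labeled:
            pred = [
                int(l)
                for d, l in zip(assignment.doc_ids, assignment.labels)
                if d in truth_topic
            ]
            gold = [truth_topic[d] for d in labeled]
            result["nmi_vs_truth"] = nmi(pred, gold)
        kept = pd.read_csv(out / "kept.csv", dtype=str)["doc_id"].tolist()
        universe = set(kept)
        gold_fd = {d for d in universe if truth_has_fd.get(d, False)}
        predicted = set(
            pd.read_csv(out / "fd_units.csv", dtype=str, keep_default_na=False)["doc_id"]
        )
        score = evaluate_extraction(predicted & universe, gold_fd, universe)
        result["extraction"] = {
            "precision": score.precision,
            "recall": score.recall,
            "f1": score.f1,
            "tp": score.tp,
            "fp": score.fp,
            "fn": score.fn,
        }
    (out / "evaluation.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    _log("evaluate", **{k: v for k, v in result.items() if not isinstance(v, dict)})
    return result


def stage_timeline(config: PipelineConfig):
    out = _out(config)
    assignment = _read_assignment(out)
    kept = pd.read_csv(out / "kept.csv", dtype=str)
    dates = dict(zip(kept["doc_id"], kept["month"]))
    months = sorted(set(dates[d] for d in assignment.doc_ids))
    timeline = monthly_proportions(assignment, dates, months=months)
    timeline_frame(timeline).to_csv(out / "timeline.csv", index=False)
    _log("timeline", months=len(timeline.months), empty_months=len(timeline.empty_months))
    return timeline


def stage_evolve(config: PipelineConfig):
    out = _out(config)
    assignment = _read_assignment(out)
    kept = pd.read_csv(out / "kept.csv", dtype=str)
    dates = dict(zip(kept["doc_id"], kept["month"]))
    timeline = stage_timeline(config)
    stages = stage_partition(timeline.months)
    emb = load_embeddings(out / "embeddings.tsv")
    overlaps = stage_overlaps(emb, assignment, dates, stages)
    events = classify_evolution(
        timeline,
        overlaps,
        threshold=config.evolution_threshold,
        inherit_min=config.inherit_min,
        branch_min=config.branch_min,
        stages=stages,
    )
    payload = [
        {
            "event_type": e.event_type,
            "stage": e.stage,
            "source_topics": e.source_topics,
            "target_topics": e.target_topics,
            "evidence": e.evidence,
        }
        for e in events
    ]
    (out / "events.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    _log("evolve", events=len(events))
    return events


MANIFEST_ARTIFACTS = [
    "cleaning_audit.csv",
    "kept.csv",
    "fd_units.csv",
    "tfidf/matrix.mtx",
    "tfidf/vocabulary.txt",
    "tfidf/doc_ids.txt",
    "term_frequencies.csv",
    "loss_history.csv",
    "embeddings.tsv",
    "elbow.csv",
    "selected_k.json",
    "assignment.csv",
    "keywords.csv",
    "evaluation.json",
    "timeline.csv",
    "events.json",
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    out = _out(config)
    stage_extract(config)  # ingest -> clean -> extract
    stage_vectorize(config)
    stage_train(config)
    if config.k == "elbow":
        stage_elbow(config)
    stage_cluster(config)
    stage_evaluate(config)
    stage_timeline(config)
    stage_evolve(config)
    checksums = {
        rel: _sha256(out / rel) for rel in MANIFEST_ARTIFACTS if (out / rel).exists()
    }
    manifest = {
        "config": config.to_dict(),
        "artifacts": checksums,
        "versions": {
            "fdmine": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
        "seed_ledger": {
            stage: derive_seed(config.seed, stage) for stage in ("train", "cluster")
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _log("run_pipeline", artifacts=len(checksums))
    return manifest
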