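"""Keyword profiles, timelines, stage partition, and the evolution
classifier."""

import numpy as np
import pytest

from fdmine.clustering_eval import ClusterAssignment
from fdmine.topic_analysis import (
    EvolutionEvent,
    TopicTimeline,
    classify_evolution,
    cluster_keywords,
    monthly_proportions,
    stage_mean_proportions,
    stage_overlaps,
    stage_partition,
)


def make_assignment(labels, k, ids=None):
    labels = np.asarray(labels)
    ids = ids or [f"d{i}" for i in range(len(labels))]
    return ClusterAssignment(ids, labels, k, "cosine", np.zeros((k, 2)), 0)


class TestClusterKeywords:
    def test_synthetic_cluster_keywords_come_from_its_vocabulary(self, small_corpus):
        from fdmine.ingest_extract import extract_corpus
        from fdmine.preprocess_vectorize import build_tfidf, tokenize_units

        docs = tokenize_units(extract_corpus(small_corpus.records))
        matrix = build_tfidf(docs, max_features=400)
        truth = [small_corpus.truth_topic[d] for d in matrix.doc_ids]
        assignment = make_assignment(truth, 3, ids=matrix.doc_ids)
        profile = cluster_keywords(matrix, assignment, top_n=5)
        for c, ranked in profile.per_cluster.items():
            for term, weight in ranked:
                assert term.startswith(f"topic{c}_")
                assert weight > 0

    def test_single_cluster_reduces_to_global_mean_order(self):
        from fdmine.preprocess_vectorize import DocTermMatrix
        import scipy.sparse as sp

        W = sp.csr_matrix(np.array([[0.9, 0.1, 0.0], [0.8, 0.2, 0.0]]))
        matrix = DocTermMatrix(["a", "b"], ["t0", "t1", "t2"], W)
        assignment = make_assignment([0, 0], 1, ids=["a", "b"])
        profile = cluster_keywords(matrix, assignment, top_n=3)
        assert [t for t, _ in profile.per_cluster[0]] == ["t0", "t1", "t2"]

    def test_identical_clusters_have_near_zero_contrast(self):
        from fdmine.preprocess_vectorize import DocTermMatrix
        import scipy.sparse as sp

        row = [0.6, 0.8, 0.0]
        W = sp.csr_matrix(np.array([row, row, row, row]))
        matrix = DocTermMatrix(["a", "b", "c", "d"], ["t0", "t1", "t2"], W)
        assignment = make_assignment([0, 1, 0, 1], 2, ids=matrix.doc_ids)
        profile = cluster_keywords(matrix, assignment, top_n=3)
        for ranked in profile.per_cluster.values():
            assert all(abs(w) < 1e-12 for _, w in ranked)

    def test_nonpositive_top_n_rejected(self, small_corpus):
        from fdmine.ingest_extract import extract_corpus
        from fdmine.preprocess_vectorize import build_tfidf, tokenize_units

        docs = tokenize_units(extract_corpus(small_corpus.records[:5]))
        matrix = build_tfidf(docs, max_features=50)
        assignment = make_assignment([0] * len(matrix.doc_ids), 1, ids=matrix.doc_ids)
        with pytest.raises(ValueError):
            cluster_keywords(matrix, assignment, top_n=0)


class TestMonthlyProportions:
    def test_hand_computed_proportions(self):
        assignment = make_assignment([0, 0, 0, 1], 2)
        dates = {f"d{i}": "2020-01" for i in range(4)}
        tl = monthly_proportions(assignment, dates)
        np.testing.assert_allclose(tl.proportions[0], [0.75, 0.25])
        assert tl.counts[0].tolist() == [3, 1]

    def test_single_cluster_proportion_one_every_month(self):
        assignment = make_assignment([0, 0, 0, 0], 1)
        dates = {"d0": "2020-01", "d1": "2020-01", "d2": "2020-02", "d3": "2020-02"}
        tl = monthly_proportions(assignment, dates)
        np.testing.assert_allclose(tl.proportions, 1.0)

    def test_rows_sum_to_one_or_flagged_empty(self):
        assignment = make_assignment([0, 1], 2)
        dates = {"d0": "2020-01", "d1": "2020-03"}
        tl = monthly_proportions(assignment, dates, months=["2020-01", "2020-02", "2020-03"])
        assert tl.empty_months == ["2020-02"]
        sums = tl.proportions.sum(axis=1)
        assert sums[0] == pytest.approx(1.0, abs=1e-9)
        assert sums[1] == 0.0

    def test_date_outside_window_names_the_document(self):
        assignment = make_assignment([0], 1, ids=["dx"])
        with pytest.raises(ValueError, match="dx"):
            monthly_proportions(assignment, {"dx": "2021-05"}, months=["2020-01"])

    def test_planted_trend_recovered_within_binomial_bounds(self):
        from fdmine.synthetic_corpus import SyntheticConfig, generate_corpus

        trend = np.array([[0.6, 0.3, 0.1], [0.2, 0.3, 0.5]])
        cfg = SyntheticConfig(n_topics=3, docs_per_month=500,
                              months=["2020-01", "2020-02"], topic_trend=trend, seed=31)
        corpus = generate_corpus(cfg)
        ids = [r.doc_id for r in corpus.records]
        labels = [corpus.truth_topic[d] for d in ids]
        dates = {r.doc_id: r.publish_date.strftime("%Y-%m") for r in corpus.records}
        tl = monthly_proportions(make_assignment(labels, 3, ids=ids), dates)
        for m in range(2):
            for t in range(3):
                sd = np.sqrt(trend[m, t] * (1 - trend[m, t]) / 500)
                assert abs(tl.proportions[m, t] - trend[m, t]) <= 3.5 * sd


class TestStagePartition:
    def test_nine_months_split_evenly(self):
        months = [f"2020-{m:02d}" for m in range(1, 10)]
        stages = stage_partition(months)
        assert [stages[m] for m in months] == (
            ["prophase"] * 3 + ["metaphase"] * 3 + ["telophase"] * 3
        )

    def test_ten_months_remainder_goes_to_earlier_blocks(self):
        months = [f"2020-{m:02d}" for m in range(1, 11)]
        stages = stage_partition(months)
        sizes = [sum(1 for m in months if stages[m] == s)
                 for s in ("prophase", "metaphase", "telophase")]
        assert sizes == [4, 3, 3]

    def test_january_to_september_window_mapping(self):
        stages = stage_partition([f"2020-{m:02d}" for m in range(1, 10)])
        assert stages["2020-01"] == stages["2020-03"] == "prophase"
        assert stages["2020-04"] == stages["2020-06"] == "metaphase"
        assert stages["2020-07"] == stages["2020-09"] == "telophase"

    def test_fewer_than_three_months_rejected(self):
        with pytest.raises(ValueError):
            stage_partition(["2020-01", "2020-02"])


def timeline_from_stage_means(stage_means, per_stage_months=3, docs_per_month=100):
    """Build a TopicTimeline whose stage-mean proportions equal the rows of
    ``stage_means`` exactly (constant within each stage)."""
    stage_means = np.asarray(stage_means)
    months, counts = [], []
    for s in range(3):
        for m in range(per_stage_months):
            months.append(f"2020-{s * per_stage_months + m + 1:02d}")
            counts.append(np.round(stage_means[s] * docs_per_month).astype(int))
    counts = np.array(counts)
    props = counts / counts.sum(axis=1, keepdims=True)
    return TopicTimeline(months=months, counts=counts, proportions=props)


class EvolutionFixture:
    """Five topics, six planted events: birth(E), division(A -> {A, D}),
    inheritance(B), inheritance(C) in the first transition; extinction(C),
    merger({A, B, D} -> A) in the second."""

    stage_means = np.array(
        [
            # A     B     C     D     E
            [0.35, 0.30, 0.30, 0.03, 0.02],  # prophase
            [0.30, 0.25, 0.20, 0.22, 0.03],  # metaphase
            [0.55, 0.20, 0.03, 0.12, 0.10],  # telophase
        ]
    )
    overlap1 = np.array(
        [
            [0.50, 0.02, 0.02, 0.45, 0.01],  # A splits to A and D
            [0.04, 0.90, 0.02, 0.02, 0.02],  # B inherits
            [0.02, 0.02, 0.92, 0.02, 0.02],  # C inherits
            [0.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0],
        ]
    )
    overlap2 = np.array(
        [
            [0.85, 0.05, 0.04, 0.03, 0.03],  # A -> A (shared target)
            [0.75, 0.20, 0.02, 0.02, 0.01],  # B -> A (merger)
            [0.0, 0.0, 0.0, 0.0, 0.0],
            [0.80, 0.02, 0.02, 0.15, 0.01],  # D -> A (merger)
            [0.0, 0.0, 0.0, 0.0, 0.0],
        ]
    )

    @classmethod
    def events(cls, **kwargs):
        tl = timeline_from_stage_means(cls.stage_means)
        return classify_evolution(tl, [cls.overlap1, cls.overlap2], **kwargs)


class TestClassifyEvolution:
    def test_fixture_event_table_reproduced_exactly(self):
        events = EvolutionFixture.events()
        table = sorted(
            (e.event_type, e.stage, tuple(e.source_topics), tuple(e.target_topics))
            for e in events
        )
        assert table == sorted(
            [
                ("birth", "telophase", (), (4,)),
                ("division", "metaphase", (0,), (0, 3)),
                ("inheritance", "metaphase", (1,), (1,)),
                ("inheritance", "metaphase", (2,), (2,)),
                ("extinction", "telophase", (2,), ()),
                ("merger", "telophase", (0, 1, 3), (0,)),
            ]
        )

    def test_each_above_threshold_topic_gets_exactly_one_event(self):
        events = EvolutionFixture.events()
        for t, stage in ((0, "metaphase"), (1, "telophase")):
            participants = []
            for e in events:
                if e.stage == stage:
                    participants.extend(e.source_topics)
                    if e.event_type == "birth":
                        participants.extend(e.target_topics)
            assert len(participants) == len(set(participants))

    def test_threshold_is_strict_boundary_value_not_a_birth(self):
        means = np.array([[0.05, 0.95], [0.05, 0.95], [0.05, 0.95]])
        tl = timeline_from_stage_means(means)
        eye = np.eye(2)
        events = classify_evolution(tl, [eye, eye])
        assert all(e.event_type != "birth" for e in events)
        # topic 0 sits exactly at the threshold: never above, so no events
        assert all(0 not in e.source_topics + e.target_topics for e in events)

    def test_unnormalized_overlap_rejected(self):
        tl = timeline_from_stage_means(EvolutionFixture.stage_means)
        bad = EvolutionFixture.overlap1 * 2.0
        with pytest.raises(ValueError):
            classify_evolution(tl, [bad, EvolutionFixture.overlap2])

    def test_determinism(self):
        e1 = EvolutionFixture.events()
        e2 = EvolutionFixture.events()
        assert [(e.event_type, e.stage, e.source_topics, e.target_topics) for e in e1] == [
            (e.event_type, e.stage, e.source_topics, e.target_topics) for e in e2
        ]

    def test_planted_birth_and_extinction_on_synthetic_corpus(self):
        """Trend 0.02 -> 0.10 births, 0.10 -> 0.02 goes extinct, the rest
        inherit, using document-flow overlaps from planted labels."""
        from fdmine.synthetic_corpus import SyntheticConfig, generate_corpus
        from fdmine.ingest_extract import extract_corpus
        from fdmine.preprocess_vectorize import build_tfidf, tokenize_units

        months = [f"2020-{m:02d}" for m in range(1, 10)]
        trend = np.zeros((9, 4))
        birth_track = np.linspace(0.02, 0.12, 9)
        death_track = np.linspace(0.12, 0.02, 9)
        trend[:, 0] = birth_track
        trend[:, 1] = death_track
        trend[:, 2] = (1 - birth_track - death_track) / 2
        trend[:, 3] = (1 - birth_track - death_track) / 2
        cfg = SyntheticConfig(n_topics=4, docs_per_month=150, months=months,
                              topic_vocab_size=40, background_vocab_size=80,
                              topic_trend=trend, seed=41)
        corpus = generate_corpus(cfg)
        units = extract_corpus(corpus.records)
        matrix = build_tfidf(tokenize_units(units), max_features=300)
        labels = [corpus.truth_topic[d] for d in matrix.doc_ids]
        assignment = make_assignment(labels, 4, ids=matrix.doc_ids)
        dates = {r.doc_id: r.publish_date.strftime("%Y-%m") for r in corpus.records}
        tl = monthly_proportions(assignment, dates, months=months)
        stages = stage_partition(months)
        overlaps = stage_overlaps(matrix, assignment, dates, stages)
        events = classify_evolution(tl, overlaps, stages=stages)
        kinds = sorted((e.event_type, e.stage) for e in events)
        births = [e for e in events if e.event_type == "birth"]
        deaths = [e for e in events if e.event_type == "extinction"]
        assert len(births) == 1 and births[0].target_topics == [0]
        assert len(deaths) == 1 and deaths[0].source_topics == [1]
        assert all(
            e.event_type in ("birth", "extinction", "inheritance") for e in events
        )


class TestStageMeans:
    def test_document_weighted_means(self):
        # uneven monthly volumes: stage mean weights months by count
        months = ["2020-01", "2020-02", "2020-03"]
        counts = np.array([[9, 1], [1, 9], [0, 0]])
        props = np.array([[0.9, 0.1], [0.1, 0.9], [0.0, 0.0]])
        tl = TopicTimeline(months=months, counts=counts, proportions=props)
        stages = {"2020-01": "prophase", "2020-02": "prophase", "2020-03": "metaphase"}
        means = stage_mean_proportions(tl, stages)
        np.testing.assert_allclose(means[0], [0.5, 0.5])
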