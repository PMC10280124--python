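"""Lloyd clustering, distortion/elbow, and the information-theoretic scores."""

import math
from collections import Counter

import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from fdmine.autoencoder import AutoencoderConfig
from fdmine.clustering_eval import (
    cluster_embeddings,
    compare_metrics,
    distortion,
    elbow_scan,
    entropy,
    mutual_information,
    nmi,
)


def oracle_nmi(a, b):
    """Brute-force contingency-table NMI in nats."""
    n = len(a)
    pa = {x: c / n for x, c in Counter(a).items()}
    pb = {y: c / n for y, c in Counter(b).items()}
    pab = {xy: c / n for xy, c in Counter(zip(a, b)).items()}
    ha = -sum(p * math.log(p) for p in pa.values())
    hb = -sum(p * math.log(p) for p in pb.values())
    mi = sum(
        p * math.log(p / (pa[x] * pb[y])) for (x, y), p in pab.items()
    )
    if ha + hb == 0:
        return 1.0
    return 2 * mi / (ha + hb)


def blobs(rng, k=3, per=40, dim=8, spread=0.05):
    """Well-separated non-negative blobs with labels."""
    centers = rng.uniform(1.0, 2.0, size=(k, dim))
    for i in range(k):
        centers[i, i % dim] += 8.0  # strong axis separation
    X = np.vstack([centers[i] + spread * rng.normal(size=(per, dim)) for i in range(k)])
    labels = np.repeat(np.arange(k), per)
    return np.abs(X), labels


class TestEntropyMiNmi:
    def test_entropy_closed_forms(self):
        assert entropy([1, 1, 1]) == 0.0
        assert entropy([0, 0, 1, 1]) == pytest.approx(math.log(2))
        assert entropy([0, 1, 2, 3]) == pytest.approx(math.log(4))

    def test_mi_identical_two_class(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(math.log(2))

    def test_mi_independent_uniform_pair_is_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_mi_symmetry_random(self, rng):
        a = rng.integers(0, 4, size=100).tolist()
        b = rng.integers(0, 3, size=100).tolist()
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a), abs=1e-12)

    def test_mi_bounded_by_entropies(self, rng):
        for _ in range(20):
            a = rng.integers(0, 5, size=80).tolist()
            b = rng.integers(0, 4, size=80).tolist()
            mi = mutual_information(a, b)
            assert -1e-12 <= mi <= min(entropy(a), entropy(b)) + 1e-12

    def test_nmi_identical_labelings(self):
        assert nmi([0, 1, 1, 2], [0, 1, 1, 2]) == pytest.approx(1.0)

    def test_nmi_single_class_convention(self):
        assert nmi([0, 0], [0, 0]) == 1.0

    def test_nmi_independent_pair_is_zero(self):
        assert nmi([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_nmi_label_permutation_invariance(self, rng):
        a = rng.integers(0, 4, size=60).tolist()
        b = rng.integers(0, 4, size=60).tolist()
        remap = {0: 3, 1: 2, 2: 0, 3: 1}
        assert nmi([remap[x] for x in a], b) == pytest.approx(nmi(a, b), abs=1e-12)

    def test_nmi_matches_oracle_and_sklearn(self, rng):
        for _ in range(50):
            a = rng.integers(0, 8, size=100).tolist()
            b = rng.integers(0, 8, size=100).tolist()
            got = nmi(a, b)
            assert got == pytest.approx(oracle_nmi(a, b), abs=1e-12)
            assert got == pytest.approx(
                normalized_mutual_info_score(a, b, average_method="arithmetic"), abs=1e-9
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0])


class TestClusterEmbeddings:
    def test_k_one_assigns_everything_to_cluster_zero(self, rng):
        X, _ = blobs(rng)
        a = cluster_embeddings(X, 1, "cosine", seed=0)
        assert set(a.labels.tolist()) == {0}

    def test_separated_blobs_recovered_exactly(self, rng):
        X, truth = blobs(rng)
        for metric in ("cosine", "braycurtis", "correlation"):
            a = cluster_embeddings(X, 3, metric, seed=0)
            assert nmi(a.labels.tolist(), truth.tolist()) == pytest.approx(1.0)

    def test_same_seed_identical_assignment(self, rng):
        X, _ = blobs(rng)
        a1 = cluster_embeddings(X, 3, "cosine", seed=9)
        a2 = cluster_embeddings(X, 3, "cosine", seed=9)
        np.testing.assert_array_equal(a1.labels, a2.labels)

    def test_no_empty_clusters(self, rng):
        X = np.abs(rng.normal(size=(30, 5))) + 0.1
        a = cluster_embeddings(X, 6, "cosine", seed=1)
        assert set(a.labels.tolist()) == set(range(6))

    def test_invalid_k_rejected(self, rng):
        X, _ = blobs(rng)
        with pytest.raises(ValueError):
            cluster_embeddings(X, 0, "cosine")
        with pytest.raises(ValueError):
            cluster_embeddings(X, len(X) + 1, "cosine")


class TestDistortion:
    def test_singleton_clusters_have_zero_distortion(self, rng):
        from fdmine.clustering_eval import ClusterAssignment

        X = rng.normal(size=(5, 3))
        a = ClusterAssignment([str(i) for i in range(5)], np.arange(5), 5, "cosine", X.copy(), 0)
        assert distortion(X, a) == 0.0

    def test_hand_computed_one_dimensional_case(self):
        from fdmine.clustering_eval import ClusterAssignment

        X = np.array([[0.0], [2.0]])
        a = ClusterAssignment(["a", "b"], np.zeros(2, dtype=int), 1, "cosine",
                              np.array([[1.0]]), 0)
        assert distortion(X, a) == pytest.approx(2.0)

    def test_merging_clusters_never_decreases_distortion(self, rng):
        from fdmine.clustering_eval import ClusterAssignment

        X, truth = blobs(rng)
        split = ClusterAssignment([str(i) for i in range(len(X))], truth, 3, "cosine",
                                  np.zeros((3, X.shape[1])), 0)
        merged_labels = np.where(truth == 2, 1, truth)
        merged = ClusterAssignment([str(i) for i in range(len(X))], merged_labels, 2,
                                   "cosine", np.zeros((2, X.shape[1])), 0)
        assert distortion(X, merged) >= distortion(X, split)

    def test_clustered_beats_random_assignment(self, rng):
        X, _ = blobs(rng)
        a = cluster_embeddings(X, 3, "cosine", seed=0)
        d_clustered = distortion(X, a)
        from fdmine.clustering_eval import ClusterAssignment

        for _ in range(50):
            labels = rng.integers(0, 3, size=len(X))
            rand = ClusterAssignment(a.doc_ids, labels, 3, "cosine", a.centers, 0)
            assert d_clustered <= distortion(X, rand)


class TestElbow:
    def test_planted_three_blobs_knee_at_three(self, rng):
        X, _ = blobs(rng, k=3, per=50)
        curve = elbow_scan(X, k_range=(2, 10), metric="cosine", seed=0)
        assert curve.knee == 3 and curve.reliable

    def test_curve_non_increasing_within_tolerance(self, rng):
        X, _ = blobs(rng, k=3, per=50)
        curve = elbow_scan(X, k_range=(2, 10), metric="cosine", seed=0)
        d = np.minimum.accumulate(curve.distortions)
        rel_viol = (np.asarray(curve.distortions) - d) / max(curve.distortions)
        assert np.all(rel_viol <= 0.05)

    def test_structureless_blob_flagged_unreliable(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 8)) + 5
        curve = elbow_scan(X, k_range=(2, 12), metric="cosine", seed=0)
        assert not curve.reliable

    def test_manual_override_respected(self, rng):
        X, _ = blobs(rng)
        curve = elbow_scan(X, k_range=(2, 6), metric="cosine", seed=0, knee_override=4)
        assert curve.knee == 4


@pytest.fixture(scope="module")
def direction_coded():
    """Topics differ in direction only; magnitudes vary wildly, so angular
    separation is the discriminating signal."""
    rng = np.random.default_rng(33)
    k, per, dim = 3, 30, 24
    dirs = np.zeros((k, dim))
    for i in range(k):
        dirs[i, i * 8 : (i + 1) * 8] = 1.0
    rows, labels = [], []
    for i in range(k):
        for _ in range(per):
            scale = rng.uniform(0.1, 10.0)
            noise = np.abs(rng.normal(0, 0.05, size=dim))
            rows.append(scale * (dirs[i] + noise))
            labels.append(i)
    return np.array(rows), labels


class TestCompareMetrics:
    def test_cosine_ranks_first_on_direction_coded_topics(self, direction_coded):
        X, labels = direction_coded
        cfg = AutoencoderConfig(input_dim=X.shape[1], hidden_dims=(20, 16, 12, 10),
                                bottleneck_dim=8, epochs=8, steps_per_epoch=80,
                                learning_rate=0.001)
        result = compare_metrics(X, cfg, k=3, reference=labels, seed=0)
        table = result.table
        assert list(table.columns[:2]) == ["metric", "nmi"]
        assert table["nmi"].is_monotonic_decreasing
        cosine_nmi = float(table.loc[table.metric == "cosine", "nmi"].iloc[0])
        assert cosine_nmi == table["nmi"].max()

    def test_self_reference_gives_nmi_one(self, direction_coded):
        X, _ = direction_coded
        cfg = AutoencoderConfig(input_dim=X.shape[1], hidden_dims=(20, 16, 12, 10),
                                bottleneck_dim=8, epochs=5, steps_per_epoch=50,
                                learning_rate=0.001)
        result = compare_metrics(X, cfg, k=3, reference=[0] * len(X), seed=0)
        # now use one assignment's own labels as the reference
        own = result.assignments["cosine"].labels.tolist()
        result2 = compare_metrics(X, cfg, k=3, reference=own, seed=0)
        assert float(
            result2.table.loc[result2.table.metric == "cosine", "nmi"].iloc[0]
        ) == pytest.approx(1.0)
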