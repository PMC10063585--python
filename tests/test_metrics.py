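"""Clustering statistics against brute-force oracles and closed forms."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score, silhouette_score

from wsdmgc import (DataValidationError, accuracy_best_map, nmi, purity,
                    silhouette, sweep_cluster_number)
from wsdmgc.metrics import best_map


def brute_force_acc(pred, true):
    """Best-map accuracy by enumerating every one-to-one mapping."""
    pred, true = np.asarray(pred), np.asarray(true)
    ids = range(max(pred.max(), true.max()) + 1)
    best = 0.0
    for perm in itertools.permutations(ids):
        best = max(best, np.mean(np.array([perm[r] for r in pred]) == true))
    return best


def brute_force_silhouette(points, labels):
    """Direct O(n^2) evaluation of the per-sample silhouette."""
    D = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    out = np.zeros(len(labels))
    for i, c in enumerate(labels):
        own = np.flatnonzero(labels == c)
        if len(own) == 1:
            continue
        a = sum(D[i, j] for j in own if j != i) / (len(own) - 1)
        b = min(np.mean([D[i, j] for j in np.flatnonzero(labels == c2)])
                for c2 in np.unique(labels) if c2 != c)
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out


label_vectors = st.lists(st.integers(0, 3), min_size=4, max_size=30)


class TestPurity:
    def test_perfect_prediction(self):
        assert purity([0, 1, 2, 0], [0, 1, 2, 0]) == 1.0

    def test_worked_example(self):
        # clusters {0,0,0},{1,1,1} over classes [0,0,1,1,2,2]: (2+2)/6
        assert purity([0, 0, 0, 1, 1, 1], [0, 0, 1, 1, 2, 2]) == \
            pytest.approx(2 / 3)

    def test_invariant_to_cluster_renaming(self):
        assert purity([1, 0, 2, 1], [0, 1, 2, 0]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(DataValidationError):
            purity([0, 1], [0, 1, 2])


class TestAccuracyBestMap:
    def test_permuted_labels_score_one(self):
        assert accuracy_best_map([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_partial_agreement(self):
        assert accuracy_best_map([0, 1, 1, 1], [0, 0, 1, 1]) == 0.75

    def test_contingency_tie_breaks_toward_low_class(self):
        # clusters agree equally under both 2-permutations
        mapping = best_map([0, 1], [0, 1])
        assert mapping[0] == 0 and mapping[1] == 1

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            pred = rng.integers(0, 4, size=n)
            true = rng.integers(0, 4, size=n)
            assert accuracy_best_map(pred, true) == \
                pytest.approx(brute_force_acc(pred, true))

    def test_at_least_plain_accuracy(self, rng):
        pred = rng.integers(0, 3, size=40)
        true = rng.integers(0, 3, size=40)
        assert accuracy_best_map(pred, true) >= np.mean(pred == true)


class TestNMI:
    def test_identical_partitions(self):
        assert nmi([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_trivial_partition_scores_zero(self):
        assert nmi([0, 0, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_both_trivial_and_equal_scores_one(self):
        assert nmi([0, 0, 0], [2, 2, 2]) == 1.0

    def test_independent_partitions_score_zero(self):
        assert nmi([0, 1, 0, 1], [0, 0, 1, 1]) == pytest.approx(0.0, abs=1e-12)

    @given(pred=label_vectors)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_sklearn_geometric_normalisation(self, pred):
        true = list(np.random.default_rng(0).integers(0, 3, size=len(pred)))
        ours = nmi(pred, true)
        ref = normalized_mutual_info_score(true, pred,
                                           average_method="geometric")
        # conventions differ only on zero-entropy partitions
        if len(set(pred)) > 1 and len(set(true)) > 1:
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_symmetric(self, rng):
        a = rng.integers(0, 3, size=25)
        b = rng.integers(0, 4, size=25)
        assert nmi(a, b) == pytest.approx(nmi(b, a))


class TestSilhouette:
    def test_two_pair_line_example(self):
        # outer points: a=1, b=10.5; inner points: a=1, b=9.5
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        S, mean = silhouette(pts, labels)
        assert np.allclose(S, [9.5 / 10.5, 8.5 / 9.5, 8.5 / 9.5, 9.5 / 10.5])
        assert mean == pytest.approx((9.5 / 10.5 + 8.5 / 9.5) / 2)

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0], [1.0], [5.0]])
        S, _ = silhouette(pts, np.array([0, 0, 1]))
        assert S[2] == 0.0

    def test_coincident_points_zero_by_convention(self):
        S, mean = silhouette(np.zeros((4, 2)), np.array([0, 0, 1, 1]))
        assert mean == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(DataValidationError):
            silhouette(np.zeros((3, 1)), np.array([0, 0, 0]))

    def test_matches_direct_oracle_and_sklearn(self, rng):
        pts = rng.normal(size=(60, 3))
        labels = rng.integers(0, 4, size=60)
        S, mean = silhouette(pts, labels)
        assert np.allclose(S, brute_force_silhouette(pts, labels), atol=1e-10)
        assert mean == pytest.approx(silhouette_score(pts, labels), abs=1e-10)

    def test_accepts_precomputed_distance_matrix(self, rng):
        pts = rng.normal(size=(20, 2))
        labels = rng.integers(0, 2, size=20)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        S1, m1 = silhouette(pts, labels)
        S2, m2 = silhouette(D, labels)
        assert np.allclose(S1, S2)


class TestRelabelingInvariance:
    @given(pred=label_vectors)
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_all_statistics_invariant_to_relabeling(self, pred):
        true = list(np.random.default_rng(1).integers(0, 3, size=len(pred)))
        relabeled = [9 - p for p in pred]
        assert purity(pred, true) == pytest.approx(purity(relabeled, true))
        assert accuracy_best_map(pred, true) == \
            pytest.approx(accuracy_best_map(relabeled, true))
        assert nmi(pred, true) == pytest.approx(nmi(relabeled, true))


class TestSweep:
    def test_single_candidate_table(self, feature_clouds):
        table, best = sweep_cluster_number(feature_clouds.X, [2], seed=0)
        assert list(table["k"]) == [2]
        assert best == 2

    def test_invalid_range_rejected(self, feature_clouds):
        with pytest.raises(DataValidationError):
            sweep_cluster_number(feature_clouds.X, [1], seed=0)

    def test_recovers_true_cluster_count_on_clean_clouds(self):
        from wsdmgc import generate_feature_dataset

        ds = generate_feature_dataset(3, 30, dim=3, centre_spacing=10.0,
                                      noise_sd=0.3, seed=0)
        table, best = sweep_cluster_number(ds.X, range(2, 6), seed=0)
        assert best == 3
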