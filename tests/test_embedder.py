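"""Metric-embedding network: loss contracts, mining, gradients, training."""

import itertools

import numpy as np
import pytest

from wsdmgc import (DataValidationError, RunConfig, TripletBatch, classify,
                    contrastive_loss, embed, fit_embedder, mine_triplets,
                    total_loss, triplet_loss)
from wsdmgc.embedder import (EmbedderError, _forward, _loss_and_grads,
                             _metric_loss_and_grad, batch_hard_triplets,
                             init_params)


def _line_embeddings(*xs):
    """1-D points as (n, 2) embeddings on the x-axis."""
    return np.array([[x, 0.0] for x in xs])


class TestTripletLoss:
    def test_all_identical_embeddings_leave_the_margin(self):
        F = np.ones((4, 3))
        batch = TripletBatch([0, 1], [1, 2], [2, 3])
        assert triplet_loss(F, batch, alpha=0.2) == pytest.approx(0.2)

    def test_satisfied_margin_is_zero(self):
        # d_ap^2 = 1, d_an^2 = 4: max(1 - 4 + 0.2, 0) = 0
        F = _line_embeddings(0.0, 1.0, 2.0)
        batch = TripletBatch([0], [1], [2])
        assert triplet_loss(F, batch, alpha=0.2) == 0.0

    def test_violated_margin_value(self):
        # d_ap^2 = 4, d_an^2 = 1: 4 - 1 + 0.2 = 3.2
        F = _line_embeddings(0.0, 2.0, 1.0)
        batch = TripletBatch([0], [1], [2])
        assert triplet_loss(F, batch, alpha=0.2) == pytest.approx(3.2)

    def test_unhinged_variant_can_go_negative(self):
        F = _line_embeddings(0.0, 1.0, 2.0)
        batch = TripletBatch([0], [1], [2])
        assert triplet_loss(F, batch, alpha=0.2, hinge=False) == \
            pytest.approx(1 - 4 + 0.2)

    def test_empty_batch_rejected(self):
        with pytest.raises(EmbedderError):
            triplet_loss(np.ones((2, 2)), TripletBatch([], [], []), 0.2)


class TestContrastiveLoss:
    def test_matched_identical_pair_is_zero(self):
        F = np.ones((2, 3))
        assert contrastive_loss([(0, 1, 1)], F, m=1.0) == 0.0

    def test_mismatched_beyond_margin_is_zero(self):
        F = _line_embeddings(0.0, 2.0)
        assert contrastive_loss([(0, 1, 0)], F, m=1.0) == 0.0

    def test_mismatched_within_margin_value(self):
        # D = 0.4, m = 1: (1/2) * 0.6^2 = 0.18
        F = _line_embeddings(0.0, 0.4)
        assert contrastive_loss([(0, 1, 0)], F, m=1.0) == pytest.approx(0.18)

    def test_empty_pairs_rejected(self):
        with pytest.raises(EmbedderError):
            contrastive_loss([], np.ones((2, 2)), 1.0)


class TestTotalLoss:
    def test_zero_weights_reduce_to_metric_loss(self):
        assert total_loss(1.3, 99.0, 99.0, 0.0, 0.0) == 1.3

    def test_weighted_combination(self):
        assert total_loss(1.0, 0.5, 10.0, 0.6, 0.04) == pytest.approx(1.7)

    def test_non_finite_rejected(self):
        with pytest.raises(EmbedderError):
            total_loss(np.inf, 0.0, 0.0, 0.5, 0.5)


class TestMining:
    def test_hardest_positive_and_nearest_negative(self):
        F = _line_embeddings(0.0, 3.0, 1.0)
        labels = np.array([0, 0, 1])
        batch = batch_hard_triplets(F, labels)
        i = list(batch.anchors).index(0)
        assert batch.positives[i] == 1   # farthest same-class
        assert batch.negatives[i] == 2   # nearest other-class

    def test_matches_brute_force_on_random_batches(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 64))
            F = rng.normal(size=(n, 4))
            labels = rng.integers(0, 4, size=n)
            if all(np.sum(labels == c) < 2 for c in np.unique(labels)):
                continue
            batch = batch_hard_triplets(F, labels)
            D2 = np.sum((F[:, None] - F[None, :]) ** 2, axis=-1)
            for a, p, nn in zip(batch.anchors, batch.positives, batch.negatives):
                pos = [j for j in range(n) if labels[j] == labels[a] and j != a]
                neg = [j for j in range(n) if labels[j] != labels[a]]
                assert D2[a, p] == max(D2[a, j] for j in pos)
                assert D2[a, nn] == min(D2[a, j] for j in neg)

    def test_singleton_classes_rejected(self):
        F = np.eye(2)
        with pytest.raises(EmbedderError):
            batch_hard_triplets(F, np.array([0, 1]))

    def test_mine_triplets_returns_valid_global_indices(self, rng):
        F = rng.normal(size=(30, 3))
        labels = np.repeat(np.arange(3), 10)
        batch = mine_triplets(F, labels, plan=(4, 4), seed=0)
        assert len(batch) > 0
        assert np.all(labels[batch.anchors] == labels[batch.positives])
        assert np.all(labels[batch.anchors] != labels[batch.negatives])
        assert np.all(batch.anchors != batch.positives)

    def test_degenerate_identical_embeddings_give_margin_loss(self):
        F = np.zeros((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        batch = batch_hard_triplets(F, labels)
        assert triplet_loss(F, batch, alpha=0.3) == pytest.approx(0.3)


class TestGradients:
    """Finite-difference checks of the analytic backpropagation."""

    def test_trunk_backprop_matches_numeric(self, rng):
        cfg = RunConfig(hidden_dims=(5,), embed_dim=4, conv_channels=(2, 4),
                        restarts=1)
        X = rng.normal(0.4, 0.2, size=(6, 8, 8))
        params = init_params((8, 8), cfg, 3, rng, input_mean=X.mean(axis=0))
        R = rng.normal(size=(6, 4))

        def linear_loss():
            F, _ = _forward(params, X)
            return float(np.sum(F * R))

        F, cache = _forward(params, X, train=True)
        from wsdmgc.embedder import _backward

        _backward(params, cache, R)
        eps = 1e-6
        for layer in params.layers:
            for p, g in zip(layer.params, layer.grads):
                flat_ix = rng.choice(p.size, size=min(4, p.size), replace=False)
                for fi in flat_ix:
                    ix = np.unravel_index(fi, p.shape)
                    orig = p[ix]
                    p[ix] = orig + eps
                    up = linear_loss()
                    p[ix] = orig - eps
                    down = linear_loss()
                    p[ix] = orig
                    numeric = (up - down) / (2 * eps)
                    assert g[ix] == pytest.approx(numeric, rel=1e-4, abs=1e-7)

    @pytest.mark.parametrize("loss", ["triplet", "contrastive"])
    def test_metric_loss_gradient_wrt_embeddings(self, loss, rng):
        cfg = RunConfig(loss=loss, alpha_margin=0.5, restarts=1)
        # well-separated points keep the mined selection stable under eps
        F = rng.normal(size=(8, 3)) * 2.0
        y = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        _, dF = _metric_loss_and_grad(F, y, cfg)
        eps = 1e-7
        for _ in range(10):
            i = int(rng.integers(0, 8))
            j = int(rng.integers(0, 3))
            Fp = F.copy()
            Fp[i, j] += eps
            up, _ = _metric_loss_and_grad(Fp, y, cfg)
            Fp[i, j] -= 2 * eps
            down, _ = _metric_loss_and_grad(Fp, y, cfg)
            numeric = (up - down) / (2 * eps)
            assert dF[i, j] == pytest.approx(numeric, rel=1e-4, abs=1e-6)


class TestEmbedAndClassify:
    def test_rows_unit_norm(self, masked_tiny, trained_tiny):
        params, _ = trained_tiny
        F = embed(masked_tiny, params)
        assert np.allclose(np.linalg.norm(F, axis=1), 1.0, atol=1e-6)

    def test_identical_inputs_identical_rows(self, masked_tiny, trained_tiny):
        params, _ = trained_tiny
        X = np.stack([masked_tiny.X[0], masked_tiny.X[0]])
        F = embed(X, params)
        assert np.array_equal(F[0], F[1])

    def test_shape_mismatch_rejected(self, trained_tiny, rng):
        params, _ = trained_tiny
        with pytest.raises(EmbedderError):
            embed(rng.normal(size=(2, 9, 9)), params)

    def test_classifier_outputs_in_class_range(self, masked_tiny, trained_tiny):
        params, _ = trained_tiny
        labels, conf = classify(masked_tiny, params)
        assert set(np.unique(labels)) <= set(range(3))
        assert np.all((conf > 0) & (conf <= 1))

    def test_train_set_separation_after_fitting(self, masked_tiny, trained_tiny):
        """Within-class embedding distances shrink below between-class ones."""
        params, _ = trained_tiny
        F = embed(masked_tiny, params)
        y = masked_tiny.y
        D = np.linalg.norm(F[:, None] - F[None, :], axis=-1)
        iu = np.triu_indices(len(y), 1)
        same = (y[:, None] == y[None, :])[iu]
        assert D[iu][same].mean() < D[iu][~same].mean()

    def test_classifier_recovers_training_labels(self, masked_tiny, trained_tiny):
        params, _ = trained_tiny
        labels, _ = classify(masked_tiny, params)
        lab = masked_tiny.labeled
        assert (labels[lab] == masked_tiny.y[lab]).mean() == 1.0


class TestFitEmbedder:
    def test_training_reduces_loss(self, trained_tiny):
        _, history = trained_tiny
        assert history["loss"].iloc[-1] <= history["loss"].iloc[0]

    def test_deterministic_given_seed(self, masked_tiny, fast_config):
        cfg = fast_config.replace(epochs=5)
        _, h1 = fit_embedder(masked_tiny, cfg)
        _, h2 = fit_embedder(masked_tiny, cfg)
        assert np.array_equal(h1["loss"].to_numpy(), h2["loss"].to_numpy())

    def test_empty_labeled_set_rejected(self, tiny_phantoms, fast_config):
        empty = tiny_phantoms.subset(np.arange(0))
        with pytest.raises(DataValidationError):
            fit_embedder(empty, fast_config)

    def test_single_class_rejected(self, tiny_phantoms, fast_config):
        one = tiny_phantoms.subset(np.flatnonzero(tiny_phantoms.y == 0))
        with pytest.raises(DataValidationError, match="2 classes"):
            fit_embedder(one, fast_config)

    def test_feature_input_uses_dense_trunk(self, feature_clouds, fast_config):
        params, _ = fit_embedder(feature_clouds, fast_config.replace(epochs=10))
        assert params.architecture["conv_channels"] == ()
        F = embed(feature_clouds, params)
        assert F.shape == (len(feature_clouds), fast_config.embed_dim)
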