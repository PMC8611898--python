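"""Architecture geometry, parameter counting, augmentation, folds, training."""

import numpy as np
import pytest

from relmap3d import layers as L
from relmap3d.network import (
    NetworkSpec,
    TrainConfig,
    augment_variants,
    apply_variant,
    build_network,
    compute_class_weights,
    count_parameters,
    cross_validate,
    predict,
    load_network,
    save_network,
    stratified_folds,
    train_fold,
    train_full,
)


class TestBuildNetwork:
    def test_pooling_chain_full_grid(self):
        """100x100x120 floor-halves to 12x12x15; flatten 12*12*15*5 = 10800."""
        spec = NetworkSpec(input_shape=(100, 100, 120))
        assert spec.pooled_shape() == (12, 12, 15)
        assert spec.flatten_size() == 10800

    def test_pooling_chain_reduced_grid(self):
        spec = NetworkSpec(input_shape=(40, 40, 48))
        assert spec.flatten_size() == 5 * 5 * 6 * 5  # 750

    def test_same_seed_same_weights(self):
        a = build_network(NetworkSpec(input_shape=(16, 16, 16)), seed=5)
        b = build_network(NetworkSpec(input_shape=(16, 16, 16)), seed=5)
        for la, lb in zip(a.layers, b.layers):
            for k in la.params:
                np.testing.assert_array_equal(la.params[k], lb.params[k])

    def test_too_small_input(self):
        with pytest.raises(ValueError, match="too small"):
            build_network(NetworkSpec(input_shape=(7, 16, 16)))

    def test_layer_order(self):
        net = build_network(NetworkSpec(input_shape=(16, 16, 16)), seed=0)
        names = [l.name for l in net.layers]
        assert names == (
            ["conv3d", "relu", "maxpool3d", "batchnorm3d"] * 3
            + ["flatten"]
            + ["dropout", "dense", "relu", "dropout", "dense", "relu", "dropout", "dense"]
        )


class TestCountParameters:
    def test_full_grid_hand_sum(self):
        """Layer-by-layer hand count: conv 140+680+680, BN 3x10, dense 691264+2080+66."""
        net = build_network(NetworkSpec(input_shape=(100, 100, 120)), seed=0)
        conv = (1 * 27 * 5 + 5) + (5 * 27 * 5 + 5) + (5 * 27 * 5 + 5)
        assert conv == 140 + 680 + 680
        bn = 3 * (5 + 5)
        dense = (10800 * 64 + 64) + (64 * 32 + 32) + (32 * 2 + 2)
        assert dense == 691264 + 2080 + 66
        total = conv + bn + dense
        assert count_parameters(net) == total
        assert round(total, -5) == 700_000

    def test_degenerate_single_dense(self):
        spec = NetworkSpec(input_shape=(1, 1, 1), n_conv_blocks=0,
                           dense_units=(2,), dropout_rate=0.0)
        net = build_network(spec, seed=0)
        assert count_parameters(net) == 1 * 2 + 2

    def test_doubling_dense1_width(self):
        base = NetworkSpec(input_shape=(16, 16, 16))
        wide = NetworkSpec(input_shape=(16, 16, 16), dense_units=(128, 32, 2))
        d = count_parameters(build_network(wide, 0)) - count_parameters(build_network(base, 0))
        flat = base.flatten_size()
        # doubling dense1 doubles its weight matrix and bias, and doubles dense2's input
        assert d == (flat * 64 + 64) + 64 * 32


class TestAugmentation:
    def test_exactly_14_pairwise_distinct(self):
        rng = np.random.default_rng(0)
        vol = rng.random((12, 12, 14))
        variants = augment_variants(vol)
        assert len(variants) == 14
        for i in range(14):
            for j in range(i + 1, 14):
                assert not np.array_equal(variants[i], variants[j])

    def test_flip_involution(self):
        rng = np.random.default_rng(1)
        vol = rng.random((11, 12, 13))
        flipped = np.flip(vol, axis=0)
        np.testing.assert_array_equal(np.flip(flipped, axis=0), vol)
        np.testing.assert_array_equal(augment_variants(vol)[7], flipped)

    def test_translation_semantics_single_voxel(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        shifted = apply_variant(vol, 1, shift=3)  # +shift along axis 0
        assert shifted[10, 7, 7] == 1.0
        assert shifted.sum() == 1.0

    def test_translation_zero_fill(self):
        vol = np.ones((12, 12, 12))
        shifted = apply_variant(vol, 2, shift=4)  # -4 along axis 0
        assert shifted[-4:].sum() == 0
        assert shifted[:-4].sum() == 8 * 144

    def test_variants_match_lazy_indexing(self):
        rng = np.random.default_rng(2)
        vol = rng.random((12, 12, 14))
        variants = augment_variants(vol, shift=10)
        for i in range(14):
            np.testing.assert_array_equal(apply_variant(vol, i, shift=10), variants[i])


class TestClassWeights:
    def test_reference_cohort_counts(self):
        w = compute_class_weights({"CN": 254, "MCI/AD": 409})
        assert round(w["CN"], 2) == 1.31
        assert round(w["MCI/AD"], 2) == 0.81

    def test_equal_counts_unit_weights(self):
        w = compute_class_weights({"a": 30, "b": 30})
        assert w == {"a": 1.0, "b": 1.0}

    def test_direct_arithmetic(self):
        w = compute_class_weights({"A": 10, "B": 40})
        assert w == {"A": 2.5, "B": 0.625}

    def test_zero_count_error(self):
        with pytest.raises(ValueError, match="no members"):
            compute_class_weights({"A": 10, "B": 0})


class TestStratifiedFolds:
    def test_reference_cohort_fold_sizes(self):
        labels = np.array(["CN"] * 254 + ["MCI"] * 220 + ["AD"] * 189)
        folds = stratified_folds(labels, k=10, seed=0)
        for f in range(10):
            te = folds == f
            assert te.sum() in (66, 67)
            assert (te & (labels == "CN")).sum() in (25, 26)
            assert (te & (labels == "MCI")).sum() == 22
            assert (te & (labels == "AD")).sum() in (18, 19)

    def test_k1_error(self):
        with pytest.raises(ValueError, match="k must be"):
            stratified_folds(np.array(["CN", "AD"] * 5), k=1)

    def test_k_exceeds_stratum(self):
        with pytest.raises(ValueError, match="stratum"):
            stratified_folds(np.array(["CN"] * 20 + ["AD"] * 3), k=5)

    def test_deterministic(self):
        labels = np.array(["CN", "MCI", "AD"] * 10)
        np.testing.assert_array_equal(
            stratified_folds(labels, k=3, seed=4), stratified_folds(labels, k=3, seed=4)
        )


class TestPredict:
    def test_probabilities_sum_to_one(self, trained_small_model, small_residuals):
        net, _ = trained_small_model
        probs, logits = predict(net, small_residuals[0])
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert probs.min() >= 0

    def test_equal_logits_give_half(self):
        spec = NetworkSpec(input_shape=(8, 8, 8), dropout_rate=0.0)
        net = build_network(spec, seed=0)
        # zero the output layer: logits become (b, b) = (0, 0)
        net.layers[-1].params["W"][:] = 0
        probs, logits = predict(net, np.random.default_rng(0).random((8, 8, 8)))
        np.testing.assert_allclose(logits, [0, 0], atol=1e-6)
        np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-6)

    def test_batch_equals_single(self, trained_small_model, small_residuals):
        net, _ = trained_small_model
        batch = small_residuals[:4]
        probs_b, _ = predict(net, batch)
        for i, vol in enumerate(batch):
            probs_s, _ = predict(net, vol)
            np.testing.assert_allclose(probs_b[i], probs_s, atol=1e-6)

    def test_shape_mismatch(self, trained_small_model):
        net, _ = trained_small_model
        with pytest.raises(ValueError, match="does not match"):
            predict(net, np.zeros((10, 10, 10)))


def test_weighted_loss_equals_duplication():
    """Class weight w (integer) equals duplicating minority samples w times.

    Compared on sum-reduced gradients of a fixed batch at initialization.
    """
    spec = NetworkSpec(input_shape=(8, 8, 8), dropout_rate=0.0)
    rng = np.random.default_rng(3)
    x = rng.random((6, 8, 8, 8, 1))
    y = np.array([1, 1, 1, 1, 0, 0])
    w = np.where(y == 0, 2.0, 1.0)

    def grads(xb, yb, wb, scale):
        net = build_network(spec, seed=9)
        logits = net.forward(xb, training=False)
        _, dlogits = L.weighted_cross_entropy(logits, yb, wb)
        g = dlogits * len(yb) * scale  # undo batch-mean reduction
        for layer in reversed(net.layers):
            g = layer.backward(g)
        return np.concatenate(
            [layer.grads[k].ravel() for layer in net.layers for k in sorted(layer.grads)]
        )

    g_weighted = grads(x, y, w, 1.0)
    x_dup = np.concatenate([x, x[y == 0]])
    y_dup = np.concatenate([y, y[y == 0]])
    g_dup = grads(x_dup, y_dup, np.ones(len(y_dup)), 1.0)
    rel = np.linalg.norm(g_weighted - g_dup) / np.linalg.norm(g_dup)
    assert rel < 1e-5


@pytest.fixture(scope="module")
def tiny_data():
    """Linearly separable noiseless two-class volumes on a tiny grid."""
    rng = np.random.default_rng(0)
    X, y = [], []
    for i in range(24):
        vol = rng.random((8, 8, 8)) * 0.1
        if i % 2:
            vol[2:6, 2:6, 2:6] += 0.8
        X.append(vol)
        y.append(i % 2)
    return np.array(X), np.array(y)


class TestTraining:
    def test_history_and_selected_epoch_contract(self, tiny_data):
        X, y = tiny_data
        spec = NetworkSpec(input_shape=(8, 8, 8))
        cfg = TrainConfig(epochs=3, augment=False, seed=0, batch_size=8)
        net = train_fold(X[:16], y[:16], X[16:], y[16:], spec, cfg)
        assert len(net.history) == 3
        accs = [h["test_balanced_accuracy"] for h in net.history]
        losses = [h["test_loss"] for h in net.history]
        best = max(range(3), key=lambda i: (accs[i], -losses[i], -i))
        assert net.selected_epoch == best + 1

    def test_empty_partition_error(self, tiny_data):
        X, y = tiny_data
        spec = NetworkSpec(input_shape=(8, 8, 8))
        with pytest.raises(ValueError, match="empty"):
            train_fold(X, y, X[:0], y[:0], spec, TrainConfig(epochs=1))

    def test_loss_decreases_on_separable_data(self, tiny_data):
        """End-of-epoch loss decreases over the first 3 epochs in >= 4/5 seeds.

        Measured on a deterministic forward pass without batch norm: at this
        tiny step count the batch-norm running-statistics warm-up would
        otherwise dominate the loss trajectory.
        """
        from relmap3d.network import _as_batch

        X, y = tiny_data
        spec = NetworkSpec(input_shape=(8, 8, 8), dropout_rate=0.0, batch_norm=False)
        ok = 0
        for seed in range(5):
            losses = []
            for epochs in (1, 2, 3):  # same seed: identical training prefixes
                cfg = TrainConfig(epochs=epochs, augment=False, seed=seed, batch_size=8)
                net = train_full(X, y, spec, cfg)
                logits = net.forward(_as_batch(X), training=False)
                loss, _ = L.weighted_cross_entropy(logits, y)
                losses.append(loss)
            ok += losses[0] > losses[1] > losses[2]
        assert ok >= 4

    def test_train_full_no_checkpointing(self, tiny_data):
        X, y = tiny_data
        net = train_full(X, y, NetworkSpec(input_shape=(8, 8, 8)),
                         TrainConfig(epochs=2, augment=False, seed=0, batch_size=8))
        assert net.selected_epoch == 2
        assert net.fold_id == "all"

    def test_cross_validate_covers_every_subject_once(self, tiny_data):
        X, y = tiny_data
        diagnoses = np.where(y == 1, "AD", "CN")
        models, metrics, folds = cross_validate(
            list(X), diagnoses, NetworkSpec(input_shape=(8, 8, 8)),
            TrainConfig(epochs=1, augment=False, seed=0, batch_size=8), k=3,
        )
        assert len(models) == 3
        assert sorted(np.unique(folds)) == [0, 1, 2]
        assert len(folds) == len(X)  # every subject assigned exactly one test fold

    def test_save_load_roundtrip(self, tiny_data, tmp_path):
        X, y = tiny_data
        net = train_full(X, y, NetworkSpec(input_shape=(8, 8, 8)),
                         TrainConfig(epochs=1, augment=False, seed=0, batch_size=8))
        save_network(net, tmp_path / "net")
        back = load_network(tmp_path / "net")
        p1, l1 = predict(net, X[0])
        p2, l2 = predict(back, X[0])
        np.testing.assert_allclose(l1, l2, atol=1e-7)
        assert back.selected_epoch == net.selected_epoch
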