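"""Relevance propagation: hand-evaluated rule examples, brute-force layer
oracles, conservation/non-negativity/linearity properties, batch-norm folding."""

import numpy as np
import pytest

from relmap3d import layers as L
from relmap3d.lrp import (
    LRPConfig,
    compute_relevance_map,
    conservation_error,
    fold_batchnorm_into_conv,
    fold_batchnorm_into_dense,
    propagate_alphabeta,
    propagate_batchnorm,
    propagate_epsilon,
    propagate_maxpool,
)
from relmap3d.network import NetworkSpec, build_network


def _dense(W, b=None):
    W = np.asarray(W, np.float64)
    layer = L.Dense(W.shape[0], W.shape[1])
    layer.params["W"] = W
    layer.params["b"] = np.zeros(W.shape[1]) if b is None else np.asarray(b, np.float64)
    return layer


class TestAlphaBetaRule:
    def test_two_input_example(self):
        """a=(1,2), w=(0.5,0.5), R=1 -> relevance shares (1/3, 2/3)."""
        layer = _dense([[0.5], [0.5]])
        R = propagate_alphabeta(layer, np.array([[1.0, 2.0]]), np.array([[1.0]]))
        np.testing.assert_allclose(R, [[1 / 3, 2 / 3]], atol=1e-12)

    def test_all_negative_weights_drop_relevance(self):
        layer = _dense([[-0.5], [-0.2]])
        R = propagate_alphabeta(layer, np.array([[1.0, 2.0]]), np.array([[1.0]]))
        np.testing.assert_array_equal(R, [[0.0, 0.0]])

    def test_conservation_positive_weights_no_bias(self):
        rng = np.random.default_rng(0)
        layer = _dense(rng.uniform(0.1, 1, (6, 4)))
        a = rng.uniform(0, 1, (3, 6))
        R_in = rng.uniform(0, 1, (3, 4))
        R = propagate_alphabeta(layer, a, R_in)
        np.testing.assert_allclose(R.sum(axis=1), R_in.sum(axis=1), atol=1e-10)

    def test_linearity_in_relevance(self):
        rng = np.random.default_rng(1)
        layer = _dense(rng.normal(size=(5, 3)))
        a = rng.uniform(0, 1, (2, 5))
        R_in = rng.uniform(0, 1, (2, 3))
        R1 = propagate_alphabeta(layer, a, R_in)
        R3 = propagate_alphabeta(layer, a, 3.0 * R_in)
        np.testing.assert_allclose(R3, 3.0 * R1, atol=1e-12)

    def test_conv_matches_unrolled_dense(self):
        """Conv alpha/beta equals the rule on the explicitly unrolled affine map."""
        rng = np.random.default_rng(2)
        shape = (4, 4, 5)
        W = rng.normal(size=(1, 3, 3, 3, 2))
        conv = L.Conv3D(1, 2)
        conv.params["W"] = W
        conv.params["b"] = np.zeros(2)
        n_in = int(np.prod(shape))
        # unroll by pushing unit impulses through the forward convolution
        M = np.zeros((n_in, n_in * 2))
        for j in range(n_in):
            e = np.zeros((1,) + shape + (1,))
            e.ravel()[j] = 1.0
            M[j] = L.conv3d_raw(e, W).ravel()
        a = rng.uniform(0, 1, (1,) + shape + (1,))
        R_in = rng.uniform(0, 1, (1,) + shape + (2,))
        dense = _dense(M)
        R_ref = propagate_alphabeta(dense, a.reshape(1, -1), R_in.reshape(1, -1))
        R = propagate_alphabeta(conv, a, R_in)
        np.testing.assert_allclose(R.reshape(1, -1), R_ref, atol=1e-9)


class TestEpsilonRule:
    def test_hand_example(self):
        """a=(2,1), w=(1,-0.5): z=1.5, shares (2/1.5, -0.5/1.5)."""
        layer = _dense([[1.0], [-0.5]])
        R = propagate_epsilon(layer, np.array([[2.0, 1.0]]), np.array([[1.0]]))
        np.testing.assert_allclose(R, [[2 / 1.5, -0.5 / 1.5]], rtol=1e-9)
        assert R.sum() == pytest.approx(1.0, rel=1e-9)  # epsilon absorption ~0

    def test_large_epsilon_absorbs_everything(self):
        layer = _dense([[1.0], [0.5]])
        R = propagate_epsilon(layer, np.array([[2.0, 1.0]]), np.array([[1.0]]),
                              epsilon=1e12)
        np.testing.assert_allclose(R, 0, atol=1e-10)

    def test_zero_preactivation_finite(self):
        layer = _dense([[1.0], [1.0]])
        R = propagate_epsilon(layer, np.array([[1.0, -1.0]]), np.array([[1.0]]))
        assert np.isfinite(R).all()


class TestMaxPool:
    def test_tie_breaks_to_lowest_linear_index(self):
        pool = L.MaxPool3D(2)
        x = np.array([0.1, 0.9, 0.3, 0.9, 0.0, 0.2, 0.4, 0.5]).reshape(1, 2, 2, 2, 1)
        pool.forward(x)
        R = propagate_maxpool(pool, x, np.array([[[[[1.0]]]]]))
        np.testing.assert_array_equal(R.ravel(), [0, 1, 0, 0, 0, 0, 0, 0])

    def test_conservation_exact(self):
        rng = np.random.default_rng(3)
        pool = L.MaxPool3D(2)
        x = rng.random((2, 8, 8, 8, 3))
        out = pool.forward(x)
        R_in = rng.random(out.shape)
        R = propagate_maxpool(pool, x, R_in)
        assert R.sum() == pytest.approx(R_in.sum(), rel=1e-12)

    def test_matches_bruteforce_argmax_routing(self):
        rng = np.random.default_rng(4)
        pool = L.MaxPool3D(2)
        x = rng.random((1, 8, 8, 8, 1))
        out = pool.forward(x)
        R_in = rng.random(out.shape)
        R = propagate_maxpool(pool, x, R_in)
        ref = np.zeros_like(x)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    win = x[0, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2, 0]
                    a, b, c = np.unravel_index(win.argmax(), (2, 2, 2))
                    ref[0, 2 * i + a, 2 * j + b, 2 * k + c, 0] = R_in[0, i, j, k, 0]
        np.testing.assert_allclose(R, ref, atol=1e-12)

    def test_odd_dimension_cropped_voxels_get_zero(self):
        rng = np.random.default_rng(5)
        pool = L.MaxPool3D(2)
        x = rng.random((1, 5, 4, 4, 1))
        out = pool.forward(x)
        R = propagate_maxpool(pool, x, np.ones(out.shape))
        assert R[0, 4].sum() == 0  # the floor-cropped slab receives nothing


class TestBatchNorm:
    def test_identity_settings_pass_through(self):
        bn = L.BatchNorm3D(2, eps=0.0)
        x = np.random.default_rng(6).normal(size=(1, 4, 4, 4, 2))
        np.testing.assert_allclose(bn.forward(x), x, atol=1e-12)
        R = np.random.default_rng(7).random((1, 4, 4, 4, 2))
        np.testing.assert_array_equal(propagate_batchnorm(bn, x, R), R)

    def test_fold_into_conv_forward_equivalence(self):
        rng = np.random.default_rng(8)
        bn = L.BatchNorm3D(3)
        bn.params["gamma"] = rng.uniform(0.5, 2, 3).astype(np.float32)
        bn.params["beta"] = rng.normal(size=3).astype(np.float32)
        bn.running_mean = rng.normal(size=3).astype(np.float32)
        bn.running_var = rng.uniform(0.5, 2, 3).astype(np.float32)
        conv = L.Conv3D(3, 4)
        conv.init_weights(rng)
        folded = fold_batchnorm_into_conv(bn, conv)
        x = rng.normal(size=(2, 6, 6, 6, 3)).astype(np.float32)
        ref = conv.forward(bn.forward(x))
        out = folded.forward(x)
        # exact one kernel radius inside the grid (padding is post-BN in ref)
        np.testing.assert_allclose(out[:, 1:-1, 1:-1, 1:-1], ref[:, 1:-1, 1:-1, 1:-1],
                                   atol=1e-5)

    def test_fold_into_dense_forward_equivalence(self):
        rng = np.random.default_rng(9)
        bn = L.BatchNorm3D(2)
        bn.params["gamma"] = rng.uniform(0.5, 2, 2).astype(np.float32)
        bn.running_mean = rng.normal(size=2).astype(np.float32)
        bn.running_var = rng.uniform(0.5, 2, 2).astype(np.float32)
        dense = L.Dense(3 * 3 * 3 * 2, 4)
        dense.init_weights(rng)
        x = rng.normal(size=(2, 3, 3, 3, 2)).astype(np.float32)
        ref = dense.forward(bn.forward(x).reshape(2, -1))
        folded = fold_batchnorm_into_dense(bn, dense, (3, 3, 3))
        np.testing.assert_allclose(folded.forward(x.reshape(2, -1)), ref, atol=1e-5)

    def test_gamma_scaling_equals_scaled_conv_relevance(self):
        """BN with gamma=2 before a conv gives the same map as doubling the
        activations into a plain conv (the alpha/beta rule is scale-covariant)."""
        rng = np.random.default_rng(10)
        conv = L.Conv3D(2, 3)
        conv.init_weights(rng)
        a = rng.uniform(0, 1, (1, 4, 4, 4, 2))
        R_in = rng.uniform(0, 1, (1, 4, 4, 4, 3))
        R_scaled_input = propagate_alphabeta(conv, 2.0 * a, R_in)
        conv2 = L.Conv3D(2, 3)
        conv2.params["W"] = conv.params["W"] * 2.0
        conv2.params["b"] = conv.params["b"]
        R_scaled_weights = propagate_alphabeta(conv2, a, R_in)
        np.testing.assert_allclose(R_scaled_input, R_scaled_weights, atol=1e-10)


class TestComputeRelevanceMap:
    def test_zero_input_zero_map(self):
        net = build_network(NetworkSpec(input_shape=(8, 8, 8)), seed=0)
        rmap = compute_relevance_map(net, np.zeros((8, 8, 8)), target_class=1)
        assert rmap.start_relevance == 0.0
        np.testing.assert_array_equal(rmap.values, 0)

    def test_invalid_target_class(self):
        net = build_network(NetworkSpec(input_shape=(8, 8, 8)), seed=0)
        with pytest.raises(ValueError, match="target class"):
            compute_relevance_map(net, np.zeros((8, 8, 8)), target_class=2)

    def test_end_to_end_matches_per_layer_oracle(self):
        """Engine output equals composed brute-force per-layer evaluations.

        Tiny network (8x8x10 input, one conv block, dense 4/2) where the conv
        is unrolled to an explicit affine matrix and every rule is evaluated
        with plain loops/matrix algebra independent of the engine's conv path.
        """
        spec = NetworkSpec(input_shape=(8, 8, 10), n_conv_blocks=1, n_filters=2,
                           dense_units=(4, 2), dropout_rate=0.0)
        net = build_network(spec, seed=1)
        rng = np.random.default_rng(2)
        vol = rng.normal(0, 0.5, (8, 8, 10)).astype(np.float32)
        rmap = compute_relevance_map(net, vol, target_class=1)

        conv, relu, pool, bn, flat, d1, r1, d2 = net.layers
        x = vol[None, ..., None]
        a0 = x
        z1 = conv.forward(a0)
        a1 = relu.forward(z1)
        a2 = pool.forward(a1)
        a3 = bn.forward(a2)
        a4 = flat.forward(a3)
        z5 = d1.forward(a4)
        a5 = r1.forward(z5)
        logits = d2.forward(a5)

        # oracle: dense epsilon rule by explicit formula
        def eps_rule(a, W, b, R):
            z = a @ W + b
            s = R / (z + 1e-10 * np.where(z >= 0, 1, -1))
            return a * (s @ W.T)

        R = np.zeros((1, 2))
        R[0, 1] = logits[0, 1]
        R = eps_rule(a5, d2.params["W"].astype(float), d2.params["b"].astype(float), R)
        R = eps_rule(a4, d1.params["W"].astype(float), d1.params["b"].astype(float), R)
        R = R.reshape(a3.shape)  # flatten inverse; BN is identity
        # pool: winner-take-all by loops
        Rp = np.zeros_like(a1, dtype=float)
        for i in range(4):
            for j in range(4):
                for k in range(5):
                    for c in range(2):
                        win = a1[0, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2,
                                 2 * k : 2 * k + 2, c]
                        a_, b_, c_ = np.unravel_index(win.argmax(), (2, 2, 2))
                        Rp[0, 2 * i + a_, 2 * j + b_, 2 * k + c_, c] = R[0, i, j, k, c]
        # conv alpha1/beta0 on the unrolled affine matrix
        n_in = 8 * 8 * 10
        M = np.zeros((n_in, n_in * 2))
        for j in range(n_in):
            e = np.zeros((1, 8, 8, 10, 1))
            e.ravel()[j] = 1.0
            M[j] = L.conv3d_raw(e, conv.params["W"].astype(float)).ravel()
        a_flat = a0.reshape(-1).astype(float)
        Rk = Rp.reshape(-1)
        contrib = a_flat[:, None] * M
        pos = np.clip(contrib, 0, None)
        denom = pos.sum(axis=0)
        s = np.divide(Rk, denom, out=np.zeros_like(Rk), where=denom != 0)
        R_vox = (pos * s).sum(axis=1).reshape(8, 8, 10)

        scale = max(1.0, np.abs(R_vox).max())
        np.testing.assert_allclose(rmap.values, R_vox, atol=1e-6 * scale)

    def test_structural_layers_conserve_exactly(self, trained_small_model,
                                                small_residuals):
        """Relevance totals are unchanged through pooling, batch norm, flatten,
        ReLU and dropout steps; only affine rule applications may absorb
        relevance (epsilon/bias shares, zero-denominator drops)."""
        net, _ = trained_small_model
        rmap = compute_relevance_map(net, small_residuals[0], 1)
        totals = rmap.layer_totals  # (name, total), output first
        scale = max(abs(t) for _, t in totals)
        structural = {"maxpool3d", "batchnorm3d", "flatten", "relu", "dropout"}
        for (_, before), (name, after) in zip(totals, totals[1:]):
            if name in structural:
                assert after == pytest.approx(before, abs=1e-9 * scale), name

    def test_sign_consistency_alpha1_beta0(self, trained_small_model, small_residuals):
        """With alpha=1/beta=0 the map carries the sign of the start relevance."""
        net, _ = trained_small_model
        cfg = LRPConfig(dense_rule="alpha_beta")
        rmap = compute_relevance_map(net, small_residuals[-1], 1, cfg)
        tol = 1e-9 * max(1.0, abs(rmap.start_relevance))
        if rmap.start_relevance >= 0:
            assert rmap.values.min() >= -tol
        else:
            assert rmap.values.max() <= tol

    def test_layer_totals_recorded_for_every_layer(self, trained_small_model,
                                                   small_residuals):
        net, _ = trained_small_model
        rmap = compute_relevance_map(net, small_residuals[0], 1)
        assert len(rmap.layer_totals) == len(net.layers) + 1

    def test_config_consistency_validation(self):
        with pytest.raises(ValueError, match="alpha - beta"):
            LRPConfig(alpha=2.0, beta=0.5)
        with pytest.raises(ValueError, match="epsilon"):
            LRPConfig(epsilon=0.0)
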