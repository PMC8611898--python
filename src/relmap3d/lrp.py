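"""Layer-wise relevance propagation (LRP) for the 3D CNN.

The engine back-distributes the pre-softmax score of a target class through
the network under the relevance-conservation principle: at every affine layer
the relevance R_k of each output neuron is shared among its inputs in
proportion to their contribution to its activation,

    R_j = sum_k  a_j w_jk^+ / sum_j' a_j' w_j'k^+  *  R_k        (alpha=1/beta=0)

for convolutional layers, and the epsilon-stabilized variant

    R_j = sum_k  a_j w_jk / (z_k + eps*sign(z_k))  *  R_k

for dense layers (z_k the pre-activation including bias; eps = 1e-10).

Implementation notes (documented, switchable where it matters):

* The alpha/beta rule is implemented in its positive-contribution form: the
  share routed through connection j->k is (a_j w_jk)^+ = a+ w+ + a- w-. For
  non-negative activations (post-ReLU) this is exactly the formula above; for
  signed inputs (residualized images, post-batch-norm activations) it is the
  standard generalization that keeps alpha=1/beta=0 maps non-negative.
* Biases are excluded from the alpha/beta denominator by default, so each
  layer conserves relevance exactly except for output neurons whose positive
  denominator is zero (their relevance is dropped, never redistributed).
* Max pooling routes each window's relevance entirely to the window's maximal
  input (ties: lowest linear index), mirroring the forward winner.
* Batch normalization at inference is a per-channel 1:1 affine map; applying
  the propagation rule to a 1:1 connection returns the incoming relevance
  unchanged, so it propagates as identity. An exact fold of frozen batch norm
  into the *following* affine layer is available for cross-checking.
* Dropout is identity at inference and in propagation; ReLU is handled
  implicitly because each affine layer's cached input is already post-ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import layers as L
from .network import TrainedNetwork


@dataclass
class LRPConfig:
    alpha: float = 1.0
    beta: float = 0.0
    epsilon: float = 1e-10
    conv_rule: str = "alpha_beta"
    dense_rule: str = "epsilon"
    bias_in_denominator: bool = False  # alpha/beta rule only
    start: str = "pre-softmax score of target class"

    def __post_init__(self) -> None:
        if abs(self.alpha - self.beta - 1.0) > 1e-12:
            raise ValueError("LRP consistency requires alpha - beta = 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class RelevanceMap:
    """Per-voxel relevance aligned to an input volume."""

    values: np.ndarray
    target_class: int
    start_relevance: float
    layer_totals: list = field(default_factory=list)  # (layer name, sum R) per step
    voxel_size_mm: float = 1.5


def _sign(z: np.ndarray) -> np.ndarray:
    """sign with the stabilization convention sign(0) := +1."""
    return np.where(z >= 0, 1.0, -1.0)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with 0 where den == 0 (zero-denominator relevance is dropped)."""
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den != 0)
    return out


# ---------------------------------------------------------------------------
# per-layer rules
# ---------------------------------------------------------------------------

def propagate_alphabeta(layer, activations, relevance_in, alpha: float = 1.0,
                        beta: float = 0.0, bias_in_denominator: bool = False):
    """alpha/beta rule on an affine layer (dense, or conv in its affine form).

    ``activations`` are the layer's true forward inputs; ``relevance_in`` is
    aligned to the layer's outputs. Positive and negative contribution pools
    are weighted alpha and -beta respectively.
    """
    a = np.asarray(activations, np.float64)
    R = np.asarray(relevance_in, np.float64)
    a_pos, a_neg = np.maximum(a, 0), np.minimum(a, 0)

    if isinstance(layer, L.Dense):
        W = np.asarray(layer.params["W"], np.float64)
        b = np.asarray(layer.params["b"], np.float64)
        W_pos, W_neg = np.maximum(W, 0), np.minimum(W, 0)

        def pool(ap, an, wp, wn, bias_part):
            z = ap @ wp + an @ wn
            den = z + bias_part if bias_in_denominator else z
            s = _safe_div(R, den)
            return ap * (s @ wp.T) + an * (s @ wn.T)

        out = alpha * pool(a_pos, a_neg, W_pos, W_neg, np.maximum(b, 0))
        if beta != 0:
            out -= beta * pool(a_pos, a_neg, W_neg, W_pos, np.minimum(b, 0))
        return out

    if isinstance(layer, L.Conv3D):
        W = np.asarray(layer.params["W"], np.float64)
        b = np.asarray(layer.params["b"], np.float64)
        W_pos, W_neg = np.maximum(W, 0), np.minimum(W, 0)

        def pool(wp, wn, bias_part):
            z = L.conv3d_raw(a_pos, wp) + L.conv3d_raw(a_neg, wn)
            den = z + bias_part if bias_in_denominator else z
            s = _safe_div(R, den)
            return a_pos * L.conv3d_raw(s, L.transpose_kernel(wp)) + a_neg * L.conv3d_raw(
                s, L.transpose_kernel(wn)
            )

        out = alpha * pool(W_pos, W_neg, np.maximum(b, 0))
        if beta != 0:
            out -= beta * pool(W_neg, W_pos, np.minimum(b, 0))
        return out

    raise TypeError(f"alpha/beta rule needs an affine layer, got {type(layer).__name__}")


def propagate_epsilon(layer, activations, relevance_in, epsilon: float = 1e-10):
    """Epsilon-stabilized rule on a dense layer (bias included in z_k)."""
    if not isinstance(layer, L.Dense):
        raise TypeError("epsilon rule is applied to dense layers")
    a = np.asarray(activations, np.float64)
    R = np.asarray(relevance_in, np.float64)
    W = np.asarray(layer.params["W"], np.float64)
    b = np.asarray(layer.params["b"], np.float64)
    z = a @ W + b
    s = R / (z + epsilon * _sign(z))
    return a * (s @ W.T)


def propagate_maxpool(layer: L.MaxPool3D, activations, relevance_in):
    """Winner-take-all routing: each window's relevance goes to its max input."""
    del activations  # the forward cache already records the winners
    return layer.route_back(np.asarray(relevance_in, np.float64))


def propagate_batchnorm(bn: L.BatchNorm3D, activations, relevance_in):
    """Identity propagation through frozen batch norm (1:1 affine map)."""
    del bn, activations
    return np.asarray(relevance_in, np.float64)


def fold_batchnorm_into_conv(bn: L.BatchNorm3D, conv: L.Conv3D) -> L.Conv3D:
    """Fold frozen BN *preceding* a convolution into that convolution.

    conv(BN(x)) == folded_conv(x) on interior voxels: the per-input-channel
    scale multiplies the kernel and the offset is contracted into the bias.
    At 'same'-padding borders the fold attributes the offset to padded taps
    too, so exact equivalence holds one kernel radius inside the grid.
    """
    scale, offset = bn.inference_scale_offset()
    folded = L.Conv3D(conv.c_in, conv.c_out, conv.kernel)
    W = conv.params["W"]
    folded.params["W"] = (W * scale[:, None, None, None, None]).astype(W.dtype)
    folded.params["b"] = (
        conv.params["b"] + np.tensordot(offset, W.sum(axis=(1, 2, 3)), axes=1)
    ).astype(W.dtype)
    return folded


def fold_batchnorm_into_dense(bn: L.BatchNorm3D, dense: L.Dense, spatial_shape) -> L.Dense:
    """Fold frozen BN (before flatten) into the following dense layer (exact)."""
    scale, offset = bn.inference_scale_offset()
    n = int(np.prod(spatial_shape)) * bn.channels
    scale_flat = np.broadcast_to(scale, tuple(spatial_shape) + (bn.channels,)).reshape(n)
    offset_flat = np.broadcast_to(offset, tuple(spatial_shape) + (bn.channels,)).reshape(n)
    folded = L.Dense(dense.n_in, dense.n_out, l2=dense.l2)
    W = dense.params["W"]
    folded.params["W"] = (W * scale_flat[:, None]).astype(W.dtype)
    folded.params["b"] = (dense.params["b"] + offset_flat @ W).astype(W.dtype)
    return folded


# ---------------------------------------------------------------------------
# end-to-end propagation
# ---------------------------------------------------------------------------

def compute_relevance_map(
    network: TrainedNetwork,
    volume,
    target_class: int = 1,
    config: LRPConfig | None = None,
) -> RelevanceMap:
    """Back-propagate the target class's pre-softmax score to input voxels.

    Runs an inference-mode forward pass to cache every layer's true input,
    starts from the target logit, and applies dense->epsilon,
    conv->alpha1/beta0, pool->winner-take-all, batch-norm/dropout->identity,
    flatten->reshape. Per-layer relevance totals are recorded for the
    conservation diagnostics.
    """
    config = config or LRPConfig()
    values = np.asarray(getattr(volume, "values", volume), np.float32)
    if values.ndim != 3:
        raise ValueError(f"expected a single 3D volume, got shape {values.shape}")
    if values.shape != network.spec.input_shape:
        raise ValueError(
            f"volume shape {values.shape} does not match network input "
            f"{network.spec.input_shape}"
        )
    n_out = network.spec.dense_units[-1]
    if not 0 <= target_class < n_out:
        raise ValueError(f"target class {target_class} outside [0, {n_out})")

    x = values[None, ..., None]
    logits = network.forward(x, training=False)
    start = float(logits[0, target_class])

    R = np.zeros((1, n_out))
    R[0, target_class] = start
    totals = [("output", float(R.sum()))]
    for layer in reversed(network.layers):
        if isinstance(layer, L.Dense):
            rule = config.dense_rule
            if rule == "epsilon":
                R = propagate_epsilon(layer, layer.input, R, config.epsilon)
            elif rule == "alpha_beta":
                R = propagate_alphabeta(
                    layer, layer.input, R, config.alpha, config.beta,
                    config.bias_in_denominator,
                )
            else:
                raise ValueError(f"unknown dense rule {rule!r}")
        elif isinstance(layer, L.Conv3D):
            if config.conv_rule != "alpha_beta":
                raise ValueError(f"unknown conv rule {config.conv_rule!r}")
            R = propagate_alphabeta(
                layer, layer.input, R, config.alpha, config.beta,
                config.bias_in_denominator,
            )
        elif isinstance(layer, L.MaxPool3D):
            R = propagate_maxpool(layer, layer.input, R)
        elif isinstance(layer, L.BatchNorm3D):
            R = propagate_batchnorm(layer, layer.input, R)
        elif isinstance(layer, L.Flatten):
            R = R.reshape(layer.input.shape)
        elif isinstance(layer, (L.ReLU, L.Dropout)):
            pass  # identity: activations feeding the next affine layer are post-ReLU
        else:  # pragma: no cover - no other layer types exist
            raise TypeError(f"no propagation rule for {type(layer).__name__}")
        totals.append((layer.name, float(R.sum())))

    return RelevanceMap(
        values=R[0, ..., 0],
        target_class=target_class,
        start_relevance=start,
        layer_totals=totals,
        voxel_size_mm=getattr(volume, "voxel_size_mm", 1.5),
    )


def conservation_error(relevance_map: RelevanceMap) -> float:
    """Relative end-to-end conservation deficit |sum(map) - start| / |start|."""
    start = relevance_map.start_relevance
    if start == 0:
        return 0.0
    return abs(float(relevance_map.values.sum()) - start) / abs(start)


def conservation_report(relevance_map: RelevanceMap) -> dict:
    """Break the conservation balance into its accounted parts.

    With biases excluded from the alpha/beta denominator, a convolutional step
    changes the relevance total only through zero-positive-denominator columns
    (relevance routed to neurons whose inputs are exactly zero -- e.g. the
    bias-driven constant activations over an all-zero image background -- is
    dropped, because no input can receive it). Dense epsilon steps absorb the
    bias and epsilon shares. The per-layer totals identify both exactly:

    start = map_sum + conv_dropped + dense_absorbed   (up to float error)
    """
    totals = relevance_map.layer_totals
    conv_dropped = 0.0
    dense_absorbed = 0.0
    for (_, before), (name, after) in zip(totals, totals[1:]):
        if name == "conv3d":
            conv_dropped += before - after
        elif name == "dense":
            dense_absorbed += before - after
    return {
        "start": relevance_map.start_relevance,
        "map_sum": float(relevance_map.values.sum()),
        "conv_dropped": conv_dropped,
        "dense_absorbed": dense_absorbed,
    }
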