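"""Minimal 3D neural-network layers on numpy.

Implements exactly what the dementia-detection network needs -- 3D "same"
convolution, ReLU, 2x2x2 floor max-pooling, batch normalization, dropout and
dense layers -- with explicit forward/backward passes and per-layer caches.
The caches double as the activation record required by the relevance
propagation engine, which is why the layers are hand-rolled rather than hidden
behind a framework graph.

Conventions: activations are channels-last, ``(batch, x, y, z, channel)``;
convolution kernels are ``(c_in, k, k, k, c_out)``; all floats float32 during
training.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _conv3d_rows(xp, W, b, out):
    """Padded-input convolution, accumulating along the contiguous voxel row.

    Fast when C_in is small (SIMD over the row); W is (Ci, k, k, k, Co).
    """
    B, D, H, Wd, Co = out.shape
    Ci, k = W.shape[0], W.shape[1]
    row = np.empty(Wd, xp.dtype)
    for n in range(B):
        for i in range(D):
            for j in range(H):
                for co in range(Co):
                    for l in range(Wd):
                        row[l] = b[co]
                    for ci in range(Ci):
                        for a in range(k):
                            for bb in range(k):
                                for c in range(k):
                                    w = W[ci, a, bb, c, co]
                                    for l in range(Wd):
                                        row[l] += w * xp[n, i + a, j + bb, l + c, ci]
                    for l in range(Wd):
                        out[n, i, j, l, co] = row[l]


@njit(cache=True, fastmath=True)
def _conv3d_patch(xp, Wt, b, k, out):
    """Padded-input convolution via a per-voxel patch buffer.

    Fast for multi-channel inputs; Wt is (Co, k^3*Ci) with patch ordering
    (a, b, c, ci) so each output channel is one unit-stride dot product.
    """
    B, D, H, Wd, Co = out.shape
    Ci = xp.shape[4]
    m_total = k * k * k * Ci
    patch = np.empty(m_total, xp.dtype)
    for n in range(B):
        for i in range(D):
            for j in range(H):
                for l in range(Wd):
                    m = 0
                    for a in range(k):
                        for bb in range(k):
                            for c in range(k):
                                for ci in range(Ci):
                                    patch[m] = xp[n, i + a, j + bb, l + c, ci]
                                    m += 1
                    for co in range(Co):
                        acc = b[co]
                        row = Wt[co]
                        for m2 in range(m_total):
                            acc += patch[m2] * row[m2]
                        out[n, i, j, l, co] = acc


@njit(cache=True, fastmath=True)
def _conv3d_grad_w_1ch(xp, dz, k, dW, db):
    """Kernel/bias gradients for a single-input-channel convolution.

    Row-contiguous accumulation; dW is (1, k, k, k, Co).
    """
    B, D, H, Wd, Co = dz.shape
    buf = np.empty((Co, Wd), dz.dtype)
    for n in range(B):
        for i in range(D):
            for j in range(H):
                for co in range(Co):
                    for l in range(Wd):
                        buf[co, l] = dz[n, i, j, l, co]
                        db[co] += dz[n, i, j, l, co]
                for a in range(k):
                    for bb in range(k):
                        for c in range(k):
                            for co in range(Co):
                                acc = dW[0, a, bb, c, co]
                                for l in range(Wd):
                                    acc += xp[n, i + a, j + bb, l + c, 0] * buf[co, l]
                                dW[0, a, bb, c, co] = acc


@njit(cache=True, fastmath=True)
def _maxpool_forward(x, out, arg):
    """2x2x2 floor max pool recording the in-window argmax (first max wins)."""
    B, D2, H2, W2, C = out.shape
    for n in range(B):
        for i in range(D2):
            for j in range(H2):
                for l in range(W2):
                    for c in range(C):
                        best = x[n, 2 * i, 2 * j, 2 * l, c]
                        besta = 0
                        m = 0
                        for a in range(2):
                            for b in range(2):
                                for cc in range(2):
                                    v = x[n, 2 * i + a, 2 * j + b, 2 * l + cc, c]
                                    if v > best:
                                        best = v
                                        besta = m
                                    m += 1
                        out[n, i, j, l, c] = best
                        arg[n, i, j, l, c] = besta


@njit(cache=True, fastmath=True)
def _maxpool_route(dout, arg, dx):
    """Scatter each window's value to its recorded winner position."""
    B, D2, H2, W2, C = dout.shape
    for n in range(B):
        for i in range(D2):
            for j in range(H2):
                for l in range(W2):
                    for c in range(C):
                        m = arg[n, i, j, l, c]
                        a = m // 4
                        b = (m // 2) % 2
                        cc = m % 2
                        dx[n, 2 * i + a, 2 * j + b, 2 * l + cc, c] = dout[n, i, j, l, c]


@njit(cache=True, fastmath=True)
def _conv3d_grad_w(xp, dz, k, dWt, db):
    """Kernel/bias gradients; dWt is (Co, k^3*Ci) in patch ordering (a,b,c,ci)."""
    B, D, H, Wd, Co = dz.shape
    Ci = xp.shape[4]
    m_total = k * k * k * Ci
    patch = np.empty(m_total, xp.dtype)
    for n in range(B):
        for i in range(D):
            for j in range(H):
                for l in range(Wd):
                    m = 0
                    for a in range(k):
                        for bb in range(k):
                            for c in range(k):
                                for ci in range(Ci):
                                    patch[m] = xp[n, i + a, j + bb, l + c, ci]
                                    m += 1
                    for co in range(Co):
                        g = dz[n, i, j, l, co]
                        db[co] += g
                        row = dWt[co]
                        for m2 in range(m_total):
                            row[m2] += patch[m2] * g


class Layer:
    """Base layer: parameter dict, gradient dict, cached forward input."""

    name = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.input: np.ndarray | None = None  # cached forward input

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def conv3d_raw(x: np.ndarray, weights: np.ndarray, bias=None) -> np.ndarray:
    """Plain 'same' 3D convolution used by forward, backward, and LRP.

    ``weights`` is (C_in, k, k, k, C_out). Runs a direct compiled loop on the
    zero-padded input (no im2col materialization).
    """
    k = weights.shape[1]
    c_in, c_out = weights.shape[0], weights.shape[-1]
    pad = k // 2
    dtype = np.result_type(x.dtype, weights.dtype)
    xp = np.pad(np.asarray(x, dtype), ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0)))
    out = np.empty(x.shape[:4] + (c_out,), dtype)
    b = np.zeros(c_out, dtype) if bias is None else np.asarray(bias, dtype)
    W = np.ascontiguousarray(weights, dtype)
    if c_in == 1:
        _conv3d_rows(xp, W, b, out)
    else:
        Wt = np.ascontiguousarray(W.transpose(4, 1, 2, 3, 0).reshape(c_out, -1))
        _conv3d_patch(xp, Wt, b, k, out)
    return out


def transpose_kernel(weights: np.ndarray) -> np.ndarray:
    """Kernel of the adjoint convolution: swap in/out channels, flip spatially."""
    return weights[:, ::-1, ::-1, ::-1, :].transpose(4, 1, 2, 3, 0).copy()


class Conv3D(Layer):
    """'Same'-padded stride-1 3D convolution."""

    name = "conv3d"

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, is_first: bool = False) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.is_first = is_first  # first layer: input gradient is never consumed
        self.params = {
            "W": np.zeros((c_in, kernel, kernel, kernel, c_out), np.float32),
            "b": np.zeros(c_out, np.float32),
        }

    def init_weights(self, rng: np.random.Generator) -> None:
        fan_in = self.c_in * self.kernel**3
        fan_out = self.c_out * self.kernel**3
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # normalized-variance uniform
        self.params["W"] = rng.uniform(-limit, limit, self.params["W"].shape).astype(np.float32)
        self.params["b"] = np.zeros(self.c_out, np.float32)

    def forward(self, x, training=False, rng=None):
        self.input = x
        return conv3d_raw(x, self.params["W"], self.params["b"])

    def backward(self, dout):
        W = self.params["W"]
        k, pad = self.kernel, self.kernel // 2
        x = np.asarray(self.input, dout.dtype)
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0)))
        db = np.zeros(self.c_out, dout.dtype)
        dout = np.ascontiguousarray(dout)
        if self.c_in == 1:
            dW = np.zeros(W.shape, dout.dtype)
            _conv3d_grad_w_1ch(xp, dout, k, dW, db)
            self.grads["W"] = dW
        else:
            dWt = np.zeros((self.c_out, k**3 * self.c_in), dout.dtype)
            _conv3d_grad_w(xp, dout, k, dWt, db)
            # undo the (a,b,c,ci) patch ordering back to (ci,a,b,c,co)
            self.grads["W"] = np.ascontiguousarray(
                dWt.reshape(self.c_out, k, k, k, self.c_in).transpose(4, 1, 2, 3, 0)
            )
        self.grads["b"] = db
        if self.is_first:
            return None  # nothing below needs a gradient
        return conv3d_raw(dout, transpose_kernel(W))


class ReLU(Layer):
    name = "relu"

    def forward(self, x, training=False, rng=None):
        self.input = x
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * (self.input > 0)


class MaxPool3D(Layer):
    """2x2x2 max pooling with floor division (odd trailing voxels dropped).

    The winning position per window is cached; ties resolve to the lowest
    linear index within the window, which the relevance engine relies on.
    """

    name = "maxpool3d"

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool
        self._arg = None
        self._in_shape = None

    def forward(self, x, training=False, rng=None):
        if self.pool != 2:
            raise NotImplementedError("only 2x2x2 pooling is supported")
        self.input = x
        B, D, H, W, C = x.shape
        D2, H2, W2 = D // 2, H // 2, W // 2
        x = np.ascontiguousarray(x)
        out = np.empty((B, D2, H2, W2, C), x.dtype)
        arg = np.empty((B, D2, H2, W2, C), np.int64)
        _maxpool_forward(x, out, arg)
        self._arg = arg
        self._in_shape = (B, D, H, W, C)
        return out

    def route_back(self, dout):
        """Scatter per-window values to the winning input positions.

        Floor-cropped trailing voxels (odd dimensions) receive zero.
        """
        dx = np.zeros(self._in_shape, dout.dtype)
        _maxpool_route(np.ascontiguousarray(dout), self._arg, dx)
        return dx

    def backward(self, dout):
        return self.route_back(dout)


class BatchNorm3D(Layer):
    """Per-channel batch normalization (statistics over batch + space)."""

    name = "batchnorm3d"

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, np.float32),
            "beta": np.zeros(channels, np.float32),
        }
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._xhat = None
        self._ivar = None

    def forward(self, x, training=False, rng=None):
        self.input = x
        axes = (0, 1, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        self._xhat, self._ivar = xhat, ivar
        self._training = training
        return self.params["gamma"] * xhat + self.params["beta"]

    def inference_scale_offset(self):
        """The frozen affine form y = scale*x + offset, per channel."""
        scale = self.params["gamma"] / np.sqrt(self.running_var + self.eps)
        offset = self.params["beta"] - scale * self.running_mean
        return scale, offset

    def backward(self, dout):
        axes = (0, 1, 2, 3)
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"]
        if not self._training:
            return dout * g * self._ivar
        N = np.prod(dout.shape[:4])
        dxhat = dout * g
        return (
            self._ivar
            / N
            * (
                N * dxhat
                - dxhat.sum(axis=axes)
                - self._xhat * (dxhat * self._xhat).sum(axis=axes)
            )
        )


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, training=False, rng=None):
        self.input = x
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.input.shape)


class Dropout(Layer):
    name = "dropout"

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        self.input = x
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    """Fully connected layer with optional L2 penalty on its weights."""

    name = "dense"

    def __init__(self, n_in: int, n_out: int, l2: float = 0.0) -> None:
        super().__init__()
        self.n_in, self.n_out, self.l2 = n_in, n_out, l2
        self.params = {
            "W": np.zeros((n_in, n_out), np.float32),
            "b": np.zeros(n_out, np.float32),
        }

    def init_weights(self, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (self.n_in + self.n_out))
        self.params["W"] = rng.uniform(-limit, limit, (self.n_in, self.n_out)).astype(np.float32)
        self.params["b"] = np.zeros(self.n_out, np.float32)

    def forward(self, x, training=False, rng=None):
        self.input = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self.input.T @ dout + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits, labels, sample_weights=None):
    """Weighted categorical cross-entropy; returns (loss, dlogits).

    Loss is the batch mean of per-sample weighted cross-entropies.
    """
    B = logits.shape[0]
    p = softmax(logits)
    w = np.ones(B, p.dtype) if sample_weights is None else np.asarray(sample_weights, p.dtype)
    ll = -np.log(np.clip(p[np.arange(B), labels], 1e-12, None))
    loss = float((w * ll).mean())
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits *= (w / B)[:, None]
    return loss, dlogits


class Adam:
    """Adaptive-moment optimizer over a list of layers."""

    def __init__(self, layers, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = b1 * self.m[i][k] + (1 - b1) * g
                self.v[i][k] = b2 * self.v[i][k] + (1 - b2) * g * g
                mhat = self.m[i][k] / corr1
                vhat = self.v[i][k] / corr2
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
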