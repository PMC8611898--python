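"""The 3D CNN classifier: architecture, augmentation, and training.

The network is the compact dementia-detection architecture: three convolution
blocks (five 3x3x3 filters each, 'same' padding, ReLU, 2x2x2 max pooling,
batch normalization), then three dropout(10%)+dense layers of 64, 32 and 2
units with ReLU on the hidden layers and softmax on the output; the last two
dense layers carry an L2 penalty. At the full 100x100x120 gray-matter grid
this comes to roughly 700k trainable parameters, most of them in the first
dense layer.

Training follows the reference protocol: Adam at learning rate 1e-4, batch
size 20, categorical cross-entropy weighted by 0.5*n/n_i class weights,
stratified 10-fold cross-validation on the three-way diagnosis (even though
the classifier is binary: controls vs. MCI+AD), optional 14-fold augmentation
(coronal-axis flip x {no shift, +/-10 voxels along each single axis}), and
best-epoch checkpoint selection on the test partition.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from . import layers as L


@dataclass
class NetworkSpec:
    """Architecture hyperparameters; defaults reproduce the reference network."""

    input_shape: tuple = (100, 100, 120)
    n_conv_blocks: int = 3
    n_filters: int = 5
    kernel: int = 3
    pool: int = 2
    batch_norm: bool = True
    dense_units: tuple = (64, 32, 2)
    dropout_rate: float = 0.10
    l2_on_last_two_dense: float = 0.01
    flip_axis: int = 0  # sagittal L/R axis for the augmentation flip

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self.dense_units = tuple(int(u) for u in self.dense_units)
        if self.dense_units[-1] != 2:
            raise ValueError("output layer must have width 2 (binary softmax)")

    def pooled_shape(self) -> tuple:
        shape = self.input_shape
        for _ in range(self.n_conv_blocks):
            shape = tuple(s // self.pool for s in shape)
        return shape

    def flatten_size(self) -> int:
        return int(np.prod(self.pooled_shape()) * self.n_filters)


@dataclass
class TrainConfig:
    """Optimization settings; defaults are the cross-validation protocol."""

    learning_rate: float = 1e-4
    batch_size: int = 20
    epochs: int = 10           # 10 CV-residualized / 20 CV-raw / 4 final-res / 8 final-raw
    class_weights: dict | None = None  # auto 0.5*n/n_i when None
    augment: str = "full"  # "full" (14 variants), "flip" (2), "none" (1)
    shift_voxels: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.augment is True:
            self.augment = "full"
        elif self.augment is False:
            self.augment = "none"
        if self.augment not in ("full", "flip", "none"):
            raise ValueError(f"unknown augment mode {self.augment!r}")

    def variant_indices(self) -> list:
        """Augmentation variant ids used per training sample.

        "full" is the reference protocol ({identity, flip} x {none, +/-shift
        per axis}); "flip" keeps only the grid-size-independent L/R flip
        (2x stream, used for reduced-grid cohorts); "none" disables
        augmentation.
        """
        if self.augment == "full":
            return list(range(14))
        if self.augment == "flip":
            return [0, 7]  # identity and pure flip
        return [0]


@dataclass
class TrainedNetwork:
    """A built (possibly trained) network: layers plus training metadata."""

    spec: NetworkSpec
    layers: list
    selected_epoch: int | None = None
    fold_id: object = None
    history: list = field(default_factory=list)

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def get_weights(self):
        return [copy.deepcopy(l.params) for l in self.layers]

    def set_weights(self, weights) -> None:
        for layer, params in zip(self.layers, weights):
            layer.params = copy.deepcopy(params)


def build_network(spec: NetworkSpec, seed: int = 0) -> TrainedNetwork:
    """Instantiate the architecture with seeded Glorot-uniform weights."""
    if any(s < spec.pool**spec.n_conv_blocks for s in spec.input_shape):
        raise ValueError(
            f"input shape {spec.input_shape} too small for "
            f"{spec.n_conv_blocks} pooling stages"
        )
    if any(s <= 0 for s in spec.input_shape):
        raise ValueError("input dimensions must be positive")
    rng = np.random.default_rng(seed)
    net_layers: list[L.Layer] = []
    c_in = 1
    for block in range(spec.n_conv_blocks):
        conv = L.Conv3D(c_in, spec.n_filters, spec.kernel, is_first=(block == 0))
        conv.init_weights(rng)
        net_layers += [conv, L.ReLU(), L.MaxPool3D(spec.pool)]
        if spec.batch_norm:
            net_layers.append(L.BatchNorm3D(spec.n_filters))
        c_in = spec.n_filters
    net_layers.append(L.Flatten())
    n_in = spec.flatten_size() if spec.n_conv_blocks else int(np.prod(spec.input_shape))
    n_dense = len(spec.dense_units)
    for i, units in enumerate(spec.dense_units):
        if spec.dropout_rate > 0:
            net_layers.append(L.Dropout(spec.dropout_rate))
        l2 = spec.l2_on_last_two_dense if i >= n_dense - 2 else 0.0
        dense = L.Dense(n_in, units, l2=l2)
        dense.init_weights(rng)
        net_layers.append(dense)
        if i < n_dense - 1:
            net_layers.append(L.ReLU())
        n_in = units
    return TrainedNetwork(spec=spec, layers=net_layers)


def count_parameters(network: TrainedNetwork) -> int:
    """Total trainable tensor sizes (conv/dense weights+biases, BN scale/shift)."""
    return int(sum(layer.n_params() for layer in network.layers))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _translate(values: np.ndarray, axis: int, shift: int) -> np.ndarray:
    """Shift along one axis, vacated voxels filled with 0 (no wrap-around)."""
    out = np.zeros_like(values)
    src = [slice(None)] * values.ndim
    dst = [slice(None)] * values.ndim
    if shift >= 0:
        dst[axis] = slice(shift, None)
        src[axis] = slice(None, values.shape[axis] - shift)
    else:
        dst[axis] = slice(None, shift)
        src[axis] = slice(-shift, None)
    out[tuple(dst)] = values[tuple(src)]
    return out


def augment_variants(values: np.ndarray, shift: int = 10, flip_axis: int = 0) -> list:
    """The 14 training variants: {identity, L/R flip} x {none, +/-shift per axis}."""
    values = np.asarray(values)
    variants = []
    for flipped in (False, True):
        base = np.flip(values, axis=flip_axis) if flipped else values
        variants.append(base.copy())
        for axis in range(3):
            for s in (shift, -shift):
                variants.append(_translate(base, axis, s))
    return variants


def apply_variant(values: np.ndarray, index: int, shift: int = 10, flip_axis: int = 0) -> np.ndarray:
    """Materialize a single augmentation variant (index 0..13) lazily."""
    if not 0 <= index < 14:
        raise ValueError("variant index must be in [0, 14)")
    flipped, local = divmod(index, 7)
    base = np.flip(values, axis=flip_axis) if flipped else values
    if local == 0:
        return np.ascontiguousarray(base)
    axis, sign = divmod(local - 1, 2)
    return _translate(base, axis, shift if sign == 0 else -shift)


# ---------------------------------------------------------------------------
# class weights and folds
# ---------------------------------------------------------------------------

def compute_class_weights(group_counts: dict) -> dict:
    """Inverse-frequency class weights w_i = 0.5 * n_total / n_i."""
    n_total = sum(group_counts.values())
    for name, n in group_counts.items():
        if n <= 0:
            raise ValueError(f"class {name!r} has no members")
    return {name: 0.5 * n_total / n for name, n in group_counts.items()}


def stratified_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each subject to one of k folds, stratified on the 3-class label.

    Stratification uses the full CN/MCI/AD diagnosis even though the
    classifier is binary, so every test partition mirrors the cohort's
    composition. Returns an integer fold id per subject.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2 (need a test partition)")
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest stratum size {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), int)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[test_idx] = fold_id
    return folds


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_batch(volumes) -> np.ndarray:
    """Stack volumes/arrays into a float32 (B, D, H, W, 1) tensor."""
    arrs = [np.asarray(getattr(v, "values", v), np.float32) for v in volumes]
    return np.stack(arrs)[..., None]


def predict(network: TrainedNetwork, volumes):
    """Class probabilities (and pre-softmax scores) for one volume or a batch.

    Returns ``(probabilities, logits)``; shape (2,) for a single volume,
    (B, 2) for a batch. Batch norm uses frozen running statistics.
    """
    arr = np.asarray(getattr(volumes, "values", volumes), np.float32)
    single = arr.ndim == 3
    batch = arr[None, ..., None] if single else _as_batch(volumes if isinstance(volumes, (list, tuple)) else arr)
    if batch.shape[1:4] != network.spec.input_shape:
        raise ValueError(
            f"volume shape {batch.shape[1:4]} does not match "
            f"network input {network.spec.input_shape}"
        )
    logits = network.forward(batch, training=False)
    probs = L.softmax(logits)
    if single:
        return probs[0], logits[0]
    return probs, logits


def _evaluate(network, X, y, class_weight_vec):
    logits = network.forward(X, training=False)
    loss, _ = L.weighted_cross_entropy(logits, y, class_weight_vec[y])
    pred = logits.argmax(axis=1)
    return balanced_accuracy_score(y, pred), loss, L.softmax(logits)[:, 1]


def train_fold(
    train_volumes,
    train_labels,
    test_volumes,
    test_labels,
    spec: NetworkSpec,
    config: TrainConfig,
    fold_id=0,
) -> TrainedNetwork:
    """Train one model on a train partition, checkpointing on the test partition.

    Labels are binary (0 = control, 1 = MCI/AD). Each epoch streams the
    (optionally 14x augmented) training sample in shuffled order; after each
    epoch the test partition is scored and the epoch with the best balanced
    accuracy (ties: lower test loss, then earlier epoch) is kept.
    """
    if len(train_volumes) == 0 or len(test_volumes) == 0:
        raise ValueError("empty train or test partition")
    Xtr, ytr = _as_batch(train_volumes), np.asarray(train_labels, int)
    Xte, yte = _as_batch(test_volumes), np.asarray(test_labels, int)
    if ytr.max() > 1 or yte.max() > 1:
        raise ValueError("labels must be binary (0 = CN, 1 = MCI/AD)")

    cw = config.class_weights or compute_class_weights(
        {0: int((ytr == 0).sum()), 1: int((ytr == 1).sum())}
    )
    cw_vec = np.array([cw[0], cw[1]], np.float32)

    rng = np.random.default_rng(config.seed)
    net = build_network(spec, seed=int(rng.integers(2**31)))
    optimizer = L.Adam(net.layers, lr=config.learning_rate)

    sample_index = [(i, v) for i in range(len(Xtr)) for v in config.variant_indices()]
    best = None  # (bal_acc, -loss, -epoch, weights)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(sample_index))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = np.stack(
                [
                    apply_variant(
                        Xtr[i, ..., 0], v, config.shift_voxels, spec.flip_axis
                    )
                    if v
                    else Xtr[i, ..., 0]
                    for i, v in (sample_index[j] for j in idx)
                ]
            )[..., None]
            yb = ytr[[sample_index[j][0] for j in idx]]
            logits = net.forward(xb, training=True, rng=rng)
            loss, dlogits = L.weighted_cross_entropy(logits, yb, cw_vec[yb])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {n_batches} "
                    f"(lr={config.learning_rate}, batch={config.batch_size})"
                )
            grad = dlogits
            for layer in reversed(net.layers):
                grad = layer.backward(grad)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        bal_acc, test_loss, _ = _evaluate(net, Xte, yte, cw_vec)
        net.history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "test_balanced_accuracy": float(bal_acc),
                "test_loss": float(test_loss),
            }
        )
        key = (bal_acc, -test_loss, -epoch)
        if best is None or key > best[0]:
            best = (key, net.get_weights())
    net.set_weights(best[1])
    net.selected_epoch = -best[0][2]
    net.fold_id = fold_id
    return net


def train_full(volumes, labels, spec: NetworkSpec, config: TrainConfig) -> TrainedNetwork:
    """Train on the whole sample for a fixed number of epochs (no checkpointing)."""
    if len(volumes) == 0:
        raise ValueError("empty training set")
    X, y = _as_batch(volumes), np.asarray(labels, int)
    cw = config.class_weights or compute_class_weights(
        {0: int((y == 0).sum()), 1: int((y == 1).sum())}
    )
    cw_vec = np.array([cw[0], cw[1]], np.float32)
    rng = np.random.default_rng(config.seed)
    net = build_network(spec, seed=int(rng.integers(2**31)))
    optimizer = L.Adam(net.layers, lr=config.learning_rate)
    sample_index = [(i, v) for i in range(len(X)) for v in config.variant_indices()]
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(sample_index))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = np.stack(
                [
                    apply_variant(X[i, ..., 0], v, config.shift_voxels, spec.flip_axis)
                    if v
                    else X[i, ..., 0]
                    for i, v in (sample_index[j] for j in idx)
                ]
            )[..., None]
            yb = y[[sample_index[j][0] for j in idx]]
            logits = net.forward(xb, training=True, rng=rng)
            loss, dlogits = L.weighted_cross_entropy(logits, yb, cw_vec[yb])
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}, batch {n_batches}")
            grad = dlogits
            for layer in reversed(net.layers):
                grad = layer.backward(grad)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        net.history.append({"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)})
    net.selected_epoch = config.epochs
    net.fold_id = "all"
    return net


def cross_validate(volumes, diagnoses, spec: NetworkSpec, config: TrainConfig, k: int = 10):
    """Stratified k-fold cross-validation of the binary CN vs. MCI+AD model.

    Returns (models, fold_metrics, fold_assignment). Every subject appears in
    exactly one test partition.
    """
    from sklearn.metrics import roc_auc_score

    diagnoses = np.asarray(diagnoses)
    binary = (diagnoses != "CN").astype(int)
    folds = stratified_folds(diagnoses, k=k, seed=config.seed)
    models, metrics = [], []
    for fold_id in range(k):
        te = folds == fold_id
        tr = ~te
        cfg = TrainConfig(**{**asdict(config), "seed": config.seed + fold_id})
        net = train_fold(
            [volumes[i] for i in np.where(tr)[0]],
            binary[tr],
            [volumes[i] for i in np.where(te)[0]],
            binary[te],
            spec,
            cfg,
            fold_id=fold_id,
        )
        probs, _ = predict(net, [volumes[i] for i in np.where(te)[0]])
        pred = probs[:, 1] >= 0.5
        metrics.append(
            {
                "fold": fold_id,
                "selected_epoch": net.selected_epoch,
                "balanced_accuracy": balanced_accuracy_score(binary[te], pred),
                "auc": roc_auc_score(binary[te], probs[:, 1]),
                "n_test": int(te.sum()),
            }
        )
        models.append(net)
    return models, metrics, folds


# ---------------------------------------------------------------------------
# persistence: weights archive + JSON sidecar
# ---------------------------------------------------------------------------

def save_network(network: TrainedNetwork, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, layer in enumerate(network.layers):
        for k, v in layer.params.items():
            arrays[f"layer{i:02d}_{k}"] = v
        if isinstance(layer, L.BatchNorm3D):
            arrays[f"layer{i:02d}_running_mean"] = layer.running_mean
            arrays[f"layer{i:02d}_running_var"] = layer.running_var
    np.savez(directory / "weights.npz", **arrays)
    meta = {
        "spec": {**asdict(network.spec)},
        "selected_epoch": network.selected_epoch,
        "fold_id": network.fold_id,
        "history": network.history,
        "layer_names": [l.name for l in network.layers],
    }
    (directory / "network.json").write_text(json.dumps(meta, indent=2))


def load_network(directory) -> TrainedNetwork:
    directory = Path(directory)
    meta = json.loads((directory / "network.json").read_text())
    spec = NetworkSpec(**meta["spec"])
    net = build_network(spec, seed=0)
    arrays = np.load(directory / "weights.npz")
    for i, layer in enumerate(net.layers):
        for k in layer.params:
            layer.params[k] = arrays[f"layer{i:02d}_{k}"]
        if isinstance(layer, L.BatchNorm3D):
            layer.running_mean = arrays[f"layer{i:02d}_running_mean"]
            layer.running_var = arrays[f"layer{i:02d}_running_var"]
    net.selected_epoch = meta["selected_epoch"]
    net.fold_id = meta["fold_id"]
    net.history = meta["history"]
    return net
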