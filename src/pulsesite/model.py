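"""A small 1-D convolutional classifier of pulse-wave acquisition site.

The network is deliberately tiny (4419 trainable parameters) because each
cardiac period is one training sample and only a few hundred periods exist
per class.  Nine layers, in order:

    AveragePooling1D(5)            1495 -> 299   (downsample the 1666 Hz input)
    Conv1D(kernel 4, 4 channels)    299 -> 296   ReLU
    MaxPooling1D(4)                 296 -> 74
    Conv1D(kernel 20, 10 channels)   74 -> 55    ReLU
    MaxPooling1D(11)                 55 -> 5
    Flatten                               50
    Dense(64)                             64     ReLU
    Dropout(0.3)                          64
    Dense(n_classes)                       5     softmax

Both convolutions are unpadded ("valid"), pooling uses stride = size.  The
implementation is pure NumPy — forward, backward and an Adam training loop
— sized for CPU-only training in seconds per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import StratifiedKFold


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    table_name = "?"
    trainable = False

    def params(self):
        return []

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class AvgPool1D(_Layer):
    table_name = "AveragePooling1D"

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train=False):
        n, L, c = x.shape
        self._in_len = L
        return x[:, : L - L % self.size, :].reshape(
            n, L // self.size, self.size, c).mean(axis=2)

    def backward(self, dy):
        n, Lo, c = dy.shape
        dx = np.repeat(dy / self.size, self.size, axis=1)
        if dx.shape[1] < self._in_len:  # truncated remainder got no gradient
            dx = np.concatenate(
                [dx, np.zeros((n, self._in_len - dx.shape[1], c), dx.dtype)], axis=1)
        return dx


class MaxPool1D(_Layer):
    table_name = "MaxPooling1D"

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train=False):
        n, L, c = x.shape
        xr = x[:, : L - L % self.size, :].reshape(n, L // self.size, self.size, c)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        n, Lo, c = dy.shape
        dxr = np.zeros((n, Lo, self.size, c), dtype=dy.dtype)
        ni, li, ci = np.ogrid[:n, :Lo, :c]
        dxr[ni, li, self._argmax, ci] = dy
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : Lo * self.size, :] = dxr.reshape(n, Lo * self.size, c)
        return dx


class Conv1D(_Layer):
    """Unpadded 1-D convolution followed by ReLU."""

    table_name = "Conv1D"
    trainable = True

    def __init__(self, kernel: int, c_in: int, c_out: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.W = (rng.standard_normal((kernel, c_in, c_out)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        xw = sliding_window_view(x, self.kernel, axis=1)  # (n, Lo, c_in, k)
        self._xw = xw
        z = np.einsum("nlck,kco->nlo", xw, self.W, optimize=True) + self.b
        self._mask = z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, dy):
        dy = dy * self._mask
        self.dW = np.einsum("nlck,nlo->kco", self._xw, dy, optimize=True)
        self.db = dy.sum(axis=(0, 1))
        dx = np.zeros_like(self._x)
        Lo = dy.shape[1]
        for k in range(self.kernel):
            dx[:, k:k + Lo, :] += dy @ self.W[k].T
        return dx

    def grads(self):
        return [self.dW, self.db]


class Flatten(_Layer):
    table_name = "Flatten"

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(_Layer):
    table_name = "Dense"
    trainable = True

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 relu: bool = True):
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.relu = relu

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        z = x @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dy):
        if self.relu:
            dy = dy * self._mask
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def grads(self):
        return [self.dW, self.db]


class Dropout(_Layer):
    table_name = "Dropout"

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass
class LayerAudit:
    """One row of the architecture table."""
    layer_type: str
    n_channels: int | None
    length_dim: int
    n_params: int


class SiteCNN:
    """The nine-layer period-window classifier."""

    def __init__(self, layers: list[_Layer], audit: list[LayerAudit],
                 input_len: int, n_classes: int, classes: Sequence[str]):
        self.layers = layers
        self.audit = audit
        self.input_len = input_len
        self.n_classes = n_classes
        self.classes = np.asarray(classes)

    def forward(self, X: np.ndarray, train: bool = False,
                skip_initial_pool: bool = False) -> np.ndarray:
        """Class probabilities for windows X of shape (n, input_len).

        ``skip_initial_pool`` feeds already average-pooled inputs of length
        ``input_len // 5`` directly to the convolutional stack.
        """
        x = np.asarray(X, dtype=np.float32)[:, :, None]
        layers = self.layers[1:] if skip_initial_pool else self.layers
        for layer in layers:
            x = layer.forward(x, train=train)
        return _softmax(x)

    predict_proba = forward

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[self.forward(X).argmax(axis=1)]

    def _backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def trainable_layers(self):
        return [l for l in self.layers if l.trainable]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.trainable_layers() for p in l.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for l in self.trainable_layers() for p in l.params()]
        for p, w in zip(flat, weights):
            p[...] = w


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(input_len: int = 1495, n_classes: int = 5,
                classes: Sequence[str] | None = None,
                seed: int = 0) -> SiteCNN:
    """Construct the classifier and audit every stage's output length.

    The pooling/convolution chain requires exact divisibility at each
    pooling stage and sufficient length at each convolution; an
    incompatible ``input_len`` is rejected with the offending stage named.
    """
    rng = np.random.default_rng(seed)
    if classes is None:
        classes = [str(i) for i in range(n_classes)]
    if len(classes) != n_classes:
        raise ValueError("len(classes) must equal n_classes")

    plan = [("AveragePooling1D", ("pool", 5)),
            ("Conv1D", ("conv", 4, 4)),
            ("MaxPooling1D", ("pool", 4)),
            ("Conv1D", ("conv", 20, 10)),
            ("MaxPooling1D", ("pool", 11)),
            ("Flatten", ("flatten",)),
            ("Dense", ("dense", 64)),
            ("Dropout", ("dropout", 0.3)),
            ("Dense", ("dense", n_classes))]

    layers: list[_Layer] = []
    audit: list[LayerAudit] = []
    length, ch = input_len, 1
    for i, (name, op) in enumerate(plan):
        if op[0] == "pool":
            size = op[1]
            if length % size != 0:
                raise ValueError(
                    f"stage {i} ({name}, size {size}): length {length} "
                    f"not divisible by pool size")
            layer = AvgPool1D(size) if name.startswith("Average") else MaxPool1D(size)
            length //= size
        elif op[0] == "conv":
            kernel, c_out = op[1], op[2]
            if length < kernel:
                raise ValueError(
                    f"stage {i} ({name}, kernel {kernel}): length {length} "
                    f"shorter than kernel")
            layer = Conv1D(kernel, ch, c_out, rng)
            length, ch = length - kernel + 1, c_out
        elif op[0] == "flatten":
            layer = Flatten()
            length, ch = length * ch, None
        elif op[0] == "dense":
            layer = Dense(length, op[1], rng,
                          relu=(op[1] != n_classes or i < len(plan) - 1))
            if i == len(plan) - 1:
                layer.relu = False  # logits feed the softmax
            length = op[1]
        else:  # dropout
            layer = Dropout(op[1], rng)
        layers.append(layer)
        audit.append(LayerAudit(name, ch, length, layer.n_params()))

    return SiteCNN(layers, audit, input_len, n_classes, classes)


def count_parameters(model: SiteCNN) -> dict:
    """Per-layer and total weight counts, summed from actual array shapes."""
    per_layer = [l.n_params() for l in model.layers if l.trainable]
    return {"per_layer": per_layer,
            "total_trainable": int(sum(per_layer)),
            "total_nontrainable": 0}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    split_level: str = "period"   # or "recording": no window of a test
                                  # recording appears in training

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("epochs", "batch_size", "learning_rate", "seed", "split_level")}


@dataclass
class FoldResult:
    fold: int
    model: SiteCNN
    test_indices: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray      # (n_test, n_classes) class probabilities
    losses: list = field(default_factory=list)


def split_folds(y: np.ndarray, k: int = 5, seed: int = 0,
                level: str = "period", groups: np.ndarray | None = None
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions (train:test 4:1 for k=5).

    ``level='recording'`` keeps all windows of a recording in the same
    fold (assigned round-robin within each class) to preclude
    within-recording leakage; it requires at least k recordings per class.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < k):
        bad = classes[counts < k][0]
        raise ValueError(f"class {bad!r} has fewer than k={k} windows")
    if level == "period":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]
    if level != "recording":
        raise ValueError("level must be 'period' or 'recording'")
    if groups is None:
        raise ValueError("recording-level split requires groups")
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    fold_of_group: dict = {}
    for c in classes:
        gs = np.unique(groups[y == c])
        if len(gs) < k:
            raise ValueError(f"class {c!r} has fewer than k={k} recordings")
        rng.shuffle(gs)
        for i, g in enumerate(gs):
            fold_of_group[g] = i % k
    folds = np.array([fold_of_group[g] for g in groups])
    idx = np.arange(len(y))
    return [(idx[folds != f], idx[folds == f]) for f in range(k)]


def train_model(model: SiteCNN, X: np.ndarray, y_idx: np.ndarray,
                cfg: TrainingConfig, rng: np.random.Generator) -> list[float]:
    """Adam + cross-entropy training loop; returns per-epoch mean losses."""
    X = np.asarray(X, dtype=np.float32)
    n = len(X)
    params = [p for l in model.trainable_layers() for p in l.params()]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps, t = 0.9, 0.999, 1e-8, 0
    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            xb = X[idx][:, :, None]
            for layer in model.layers:
                xb = layer.forward(xb, train=True)
            probs = _softmax(xb)
            yb = y_idx[idx]
            batch_loss = -np.mean(np.log(probs[np.arange(len(idx)), yb] + 1e-12))
            if not np.isfinite(batch_loss):
                raise TrainingDivergence("non-finite training loss")
            epoch_loss += batch_loss * len(idx)
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), yb] -= 1.0
            model._backward(dlogits / len(idx))
            grads = [g for l in model.trainable_layers() for g in l.grads()]
            t += 1
            for p, g, mi, vi in zip(params, grads, m, v):
                mi[...] = b1 * mi + (1 - b1) * g
                vi[...] = b2 * vi + (1 - b2) * g * g
                mhat = mi / (1 - b1**t)
                vhat = vi / (1 - b2**t)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        losses.append(epoch_loss / n)
    return losses


def train_cv(X: np.ndarray, y: np.ndarray, cfg: TrainingConfig | None = None,
             k: int = 5, groups: np.ndarray | None = None,
             classes: Sequence[str] | None = None) -> list[FoldResult]:
    """k-fold cross-validation; every window gets one held-out prediction."""
    cfg = cfg or TrainingConfig()
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    classes = np.asarray(classes)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_to_idx[c] for c in y])

    folds = split_folds(y, k=k, seed=cfg.seed, level=cfg.split_level,
                        groups=groups)
    results = []
    for f, (tr, te) in enumerate(folds):
        fold_seed = (cfg.seed * 1000003 + f) % (2**31)
        model = build_model(X.shape[1], len(classes), classes=classes,
                            seed=fold_seed)
        rng = np.random.default_rng(fold_seed + 1)
        losses = train_model(model, X[tr], y_idx[tr], cfg, rng)
        scores = model.forward(X[te])
        results.append(FoldResult(
            fold=f, model=model, test_indices=te, y_true=y[te],
            y_pred=classes[scores.argmax(axis=1)], scores=scores,
            losses=losses))
    return results


def save_weights(model: SiteCNN, path) -> None:
    """Portable plain-text weight archive (JSON of nested lists)."""
    import json
    data = {"input_len": model.input_len, "n_classes": model.n_classes,
            "classes": model.classes.tolist(),
            "weights": [w.tolist() for w in model.get_weights()]}
    with open(path, "w") as fh:
        json.dump(data, fh)


def load_weights(path) -> SiteCNN:
    import json
    with open(path) as fh:
        data = json.load(fh)
    model = build_model(data["input_len"], data["n_classes"],
                        classes=data["classes"])
    model.set_weights([np.asarray(w, dtype=np.float32)
                       for w in data["weights"]])
    return model
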