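"""Scaled-down SFCN-style 3D convolutional classifier, in pure NumPy.

The stack is a VGG-like sequence of conv3d -> batchnorm -> ReLU blocks with
stride-2 average pooling between blocks, a global average pool, and a single
dense output unit with a sigmoid.  Implemented directly on NumPy arrays (no
deep-learning framework is assumed) so that the relevance-propagation engine
has full access to every linear map, and so that batch-norm fusion and sigmoid
removal are exact, inspectable operations.

Tensors are ``(N, C, D, H, W)``.  All convolutions are stride-1, odd-kernel,
"same" zero padding, which keeps the relevance grid aligned with the input.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# linear primitives


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) -> (N*D*H*W, C*k^3) patch matrix (same padding)."""
    p = k // 2
    n, c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # (N, C, D, H, W, k, k, k) -> (N, D, H, W, C, k, k, k); reshape copies
    return win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * w, c * k**3)


def _conv_from_cols(cols: np.ndarray, w: np.ndarray, b, spatial, n) -> np.ndarray:
    o = w.shape[0]
    wm = w.reshape(o, -1).T.astype(cols.dtype, copy=False)
    out = cols @ wm
    if b is not None:
        out += b.astype(cols.dtype, copy=False)
    return out.reshape((n,) + spatial + (o,)).transpose(0, 4, 1, 2, 3)


def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Stride-1 same-padded 3D convolution. w: (out_c, in_c, k, k, k)."""
    k = w.shape[-1]
    return _conv_from_cols(_im2col(x, k), w, b, x.shape[2:], x.shape[0])


def conv3d_transpose(g: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`conv3d` with respect to its input."""
    wt = np.ascontiguousarray(np.flip(w, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4))
    return conv3d(g, wt)


def _conv3d_grad_w(cols: np.ndarray, g: np.ndarray, shape) -> np.ndarray:
    o = g.shape[1]
    gm = g.transpose(0, 2, 3, 4, 1).reshape(-1, o)
    return (cols.T @ gm).T.reshape(shape)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


# ---------------------------------------------------------------------------
# layers


class Layer:
    kind = "abstract"

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self):
        return {}

    def spec(self) -> dict:
        return {"kind": self.kind}


class Conv3d(Layer):
    kind = "conv3d"

    def __init__(self, in_c, out_c, k=3, rng=None):
        self.in_c, self.out_c, self.k = in_c, out_c, k
        if rng is not None:
            fan_in = in_c * k**3
            fan_out = out_c * k**3
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.w = rng.uniform(-limit, limit,
                                 size=(out_c, in_c, k, k, k)).astype(np.float32)
        else:
            self.w = np.zeros((out_c, in_c, k, k, k), dtype=np.float32)
        self.b = np.zeros(out_c, dtype=np.float32)

    def forward(self, x, training=False):
        cols = _im2col(x, self.k)
        self._cols = cols if training else None
        return _conv_from_cols(cols, self.w, self.b, x.shape[2:], x.shape[0])

    def backward(self, g):
        self.gw = _conv3d_grad_w(self._cols, g, self.w.shape)
        self.gb = g.sum(axis=(0, 2, 3, 4))
        self._cols = None
        return conv3d_transpose(g, self.w)

    # LRP hooks: apply the layer's linear map (optionally with modified
    # weights/bias) and its adjoint.
    def lin(self, a, w=None, b=None):
        return conv3d(a, self.w if w is None else w, b)

    def lin_t(self, s, w=None):
        return conv3d_transpose(s, self.w if w is None else w)

    def weight_parts(self):
        return np.maximum(self.w, 0), np.minimum(self.w, 0)

    def ones_weights(self):
        return np.ones_like(self.w)

    def bias(self):
        return self.b

    def params(self):
        return {"w": self.w, "b": self.b}

    def n_params(self):
        return self.w.size + self.b.size

    def spec(self):
        return {"kind": self.kind, "in_channels": self.in_c,
                "out_channels": self.out_c, "kernel": self.k, "padding": "same"}


class BatchNorm3d(Layer):
    kind = "batchnorm"

    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x, training=False):
        if training:
            axes = (0, 2, 3, 4)
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._xhat = (x - mu[None, :, None, None, None]) / np.sqrt(
                var[None, :, None, None, None] + self.eps
            )
            self._var = var
            self._n = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
            return self.gamma[None, :, None, None, None] * self._xhat + self.beta[
                None, :, None, None, None
            ]
        mu, var = self.running_mean, self.running_var
        xhat = (x - mu[None, :, None, None, None]) / np.sqrt(
            var[None, :, None, None, None] + self.eps
        )
        return self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]

    def backward(self, g):
        xhat, n = self._xhat, self._n
        axes = (0, 2, 3, 4)
        self.ggamma = (g * xhat).sum(axis=axes)
        self.gbeta = g.sum(axis=axes)
        gam = self.gamma[None, :, None, None, None]
        inv = 1.0 / np.sqrt(self._var[None, :, None, None, None] + self.eps)
        gsum = g.sum(axis=axes, keepdims=True)
        gxsum = (g * xhat).sum(axis=axes, keepdims=True)
        return gam * inv / n * (n * g - gsum - xhat * gxsum)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def n_params(self):
        return 2 * self.c

    def spec(self):
        return {"kind": self.kind, "channels": self.c, "eps": self.eps}


class ReLU(Layer):
    kind = "activation"

    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, g):
        return g * self._mask

    def spec(self):
        return {"kind": self.kind, "activation": "relu"}


class AvgPool3d(Layer):
    """2x2x2 stride-2 average pooling — a fixed-weight linear map."""

    kind = "pool"

    def forward(self, x, training=False):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"pooling requires even spatial dims, got {(d, h, w)}")
        self._in_shape = x.shape
        return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))

    def backward(self, g):
        return self._unpool(g) / 8.0

    @staticmethod
    def _unpool(g):
        return np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4)

    # LRP hooks (fixed nonnegative weights 1/8, no bias)
    def lin(self, a, w=None, b=None):
        n, c, d, h, w_ = a.shape
        return a.reshape(n, c, d // 2, 2, h // 2, 2, w_ // 2, 2).mean(axis=(3, 5, 7))

    def lin_t(self, s, w=None):
        return self._unpool(s) / 8.0

    def spec(self):
        return {"kind": self.kind, "window": 2, "stride": 2, "mode": "average"}


class GlobalAvgPool(Layer):
    kind = "global-pool"

    def forward(self, x, training=False):
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, g):
        v = int(np.prod(self._spatial))
        return np.broadcast_to(
            g[:, :, None, None, None], g.shape + self._spatial
        ).copy() / v

    def lin(self, a, w=None, b=None):
        self._spatial = a.shape[2:]
        return a.mean(axis=(2, 3, 4))

    def lin_t(self, s, w=None):
        v = int(np.prod(self._spatial))
        return np.broadcast_to(s[:, :, None, None, None], s.shape + self._spatial).copy() / v

    def spec(self):
        return {"kind": self.kind, "mode": "average"}


class Flatten(Layer):
    """Reshape (N, C, D, H, W) -> (N, C*D*H*W); used by toy dense models."""

    kind = "flatten"

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def lin(self, a, w=None, b=None):
        self._shape = a.shape
        return a.reshape(a.shape[0], -1)

    def lin_t(self, s, w=None):
        return s.reshape(self._shape)

    def spec(self):
        return {"kind": self.kind}


class Dense(Layer):
    kind = "dense"

    def __init__(self, in_f, out_f, rng=None):
        self.in_f, self.out_f = in_f, out_f
        if rng is not None:
            limit = np.sqrt(6.0 / (in_f + out_f))
            self.w = rng.uniform(-limit, limit, size=(in_f, out_f)).astype(np.float32)
        else:
            self.w = np.zeros((in_f, out_f), dtype=np.float32)
        self.b = np.zeros(out_f, dtype=np.float32)

    def forward(self, x, training=False):
        self._x = x if training else None
        return x @ self.w + self.b

    def backward(self, g):
        self.gw = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.w.T

    def lin(self, a, w=None, b=None):
        out = a @ (self.w if w is None else w)
        if b is not None:
            out = out + b
        return out

    def lin_t(self, s, w=None):
        return s @ (self.w if w is None else w).T

    def weight_parts(self):
        return np.maximum(self.w, 0), np.minimum(self.w, 0)

    def ones_weights(self):
        return np.ones_like(self.w)

    def bias(self):
        return self.b

    def params(self):
        return {"w": self.w, "b": self.b}

    def n_params(self):
        return self.w.size + self.b.size

    def spec(self):
        return {"kind": "dense-output" if self.out_f == 1 else "dense",
                "in_features": self.in_f, "out_features": self.out_f}


_TRAINABLE = (Conv3d, Dense, BatchNorm3d)


# ---------------------------------------------------------------------------
# model


@dataclass
class ClassifierModel:
    """Ordered layer stack ending in a single output unit.

    ``has_sigmoid`` selects the output scale: sigmoid probability ``yhat`` in
    [0,1], or the unbounded logit after :func:`strip_sigmoid`.
    """

    layers: list
    has_sigmoid: bool = True
    trained: bool = False
    fold_id: int | None = None
    config: dict = field(default_factory=dict)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        out = x[:, 0]
        return sigmoid(out) if self.has_sigmoid else out

    def predict(self, volumes) -> np.ndarray:
        x = _as_batch(volumes)
        return self.forward(x, training=False)

    def logits(self, volumes) -> np.ndarray:
        x = _as_batch(volumes)
        for layer in self.layers:
            x = layer.forward(x, training=False)
        return x[:, 0]

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers if hasattr(l, "n_params"))

    def manifest(self) -> dict:
        """Backend-neutral architecture manifest."""
        return {
            "layers": [l.spec() for l in self.layers],
            "output_activation": "sigmoid" if self.has_sigmoid else "linear",
            "n_params": self.n_params(),
            "trained": self.trained,
            "fold_id": self.fold_id,
            "config": dict(self.config),
        }

    def clone(self) -> "ClassifierModel":
        return copy.deepcopy(self)

    def get_weights(self):
        return [copy.deepcopy(l.params()) for l in self.layers]

    def set_weights(self, weights):
        for layer, w in zip(self.layers, weights):
            for k, v in w.items():
                setattr(layer, k, v.copy())


def _as_batch(volumes) -> np.ndarray:
    v = np.asarray(volumes, dtype=np.float64)
    if v.ndim == 3:
        v = v[None]
    if v.ndim == 4:
        v = v[:, None]
    return v


def build_model(
    grid: int = 48,
    blocks: int = 5,
    base_channels: int = 8,
    seed: int = 0,
    max_channels: int = 64,
) -> ClassifierModel:
    """Deterministic scaled-down SFCN-style stack.

    ``blocks`` conv-bn-relu blocks; the first ``blocks - 1`` are followed by a
    stride-2 average pool, so the grid must be divisible by ``2**(blocks-1)``.
    Channel widths double per block, capped at ``max_channels``.
    """
    if blocks < 1:
        raise ValueError("blocks must be >= 1")
    if grid % 2 ** (blocks - 1) != 0:
        raise ValueError(
            f"grid {grid} not divisible by 2**(blocks-1) = {2 ** (blocks - 1)}"
        )
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    in_c = 1
    for i in range(blocks):
        out_c = min(base_channels * 2**i, max_channels)
        layers.append(Conv3d(in_c, out_c, k=3, rng=rng))
        layers.append(BatchNorm3d(out_c))
        layers.append(ReLU())
        if i < blocks - 1:
            layers.append(AvgPool3d())
        in_c = out_c
    layers.append(GlobalAvgPool())
    layers.append(Dense(in_c, 1, rng=rng))
    return ClassifierModel(
        layers=layers,
        has_sigmoid=True,
        config={
            "grid": grid,
            "blocks": blocks,
            "base_channels": base_channels,
            "max_channels": max_channels,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# model surgery


def strip_sigmoid(model: ClassifierModel) -> ClassifierModel:
    """Return the model in logit mode (sigmoid removed from the output)."""
    if not model.has_sigmoid:
        warnings.warn("model already in logit mode; no-op", stacklevel=2)
        return model
    out = model.clone()
    out.has_sigmoid = False
    return out


def fuse_batchnorm(model: ClassifierModel) -> ClassifierModel:
    """Fold every batch-norm layer into its preceding convolution.

    Uses the (inference-mode) running statistics; the fused model has no
    batch-norm layers and matches the original's outputs up to float error.
    """
    out = model.clone()
    fused: list[Layer] = []
    for layer in out.layers:
        if isinstance(layer, BatchNorm3d):
            if not fused or not isinstance(fused[-1], Conv3d):
                raise ValueError("batchnorm with no preceding conv layer")
            conv = fused[-1]
            scale = layer.gamma / np.sqrt(layer.running_var + layer.eps)
            conv.w = conv.w * scale[:, None, None, None, None]
            conv.b = (conv.b - layer.running_mean) * scale + layer.beta
        else:
            fused.append(layer)
    out.layers = fused
    return out


# ---------------------------------------------------------------------------
# fold construction and training


def make_stratified_folds(
    metadata: pd.DataFrame, k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Subject-disjoint folds stratified on (label, site, sex, 10-year age bin).

    ``metadata`` has one row per volume with subject_id, label, site, sex, age;
    all rows of a subject share a fold by construction (stratification happens
    at the subject level using each subject's first row).
    """
    subj = metadata.groupby("subject_id").first().reset_index()
    rng = np.random.default_rng(seed)
    assign: dict[str, int] = {}
    offset = 0
    strata = subj.assign(age_bin=(subj["age"] // 10).astype(int)).groupby(
        ["label", "site", "sex", "age_bin"], sort=True
    )
    for _, grp in strata:
        ids = grp["subject_id"].tolist()
        rng.shuffle(ids)
        for j, sid in enumerate(ids):
            assign[sid] = (j + offset) % k
        offset += len(ids)
    return assign


def _augment_random_box(x, width, rng, prob=0.5, max_boxes=1):
    """Replace random cubes with U(0,1) noise (on a copy).

    With probability ``prob`` per sample, 1..max_boxes cubes are injected;
    multiple boxes train invariance to the iterated occlusion used at
    evaluation time.
    """
    x = x.copy()
    d = x.shape[-1]
    w = min(width, d)
    for i in range(x.shape[0]):
        if rng.random() >= prob:
            continue
        for _ in range(int(rng.integers(1, max_boxes + 1))):
            lo = rng.integers(0, d - w + 1, size=3)
            sl = (i, 0, slice(lo[0], lo[0] + w), slice(lo[1], lo[1] + w),
                  slice(lo[2], lo[2] + w))
            x[sl] = rng.uniform(0.0, 1.0, size=(w, w, w))
    return x


def _bce(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _sgd_epoch(model, x, y, batch, lr, weight_decay, rng, augment, augment_width,
               augment_prob, augment_max_boxes):
    order = rng.permutation(len(x))
    for start in range(0, len(x), batch):
        idx = order[start : start + batch]
        xb, yb = x[idx], y[idx]
        if augment:
            xb = _augment_random_box(xb, augment_width, rng, prob=augment_prob,
                                     max_boxes=augment_max_boxes)
        h = xb
        for layer in model.layers:
            h = layer.forward(h, training=True)
        logit = h[:, 0]
        p = sigmoid(logit)
        g = ((p - yb) / len(idx))[:, None].astype(np.float32)  # d(BCE)/d(logit)
        for layer in reversed(model.layers):
            g = layer.backward(g)
        for layer in model.layers:
            if isinstance(layer, (Conv3d, Dense)):
                layer.w -= lr * (layer.gw + weight_decay * layer.w)
                layer.b -= lr * layer.gb
            elif isinstance(layer, BatchNorm3d):
                layer.gamma -= lr * layer.ggamma
                layer.beta -= lr * layer.gbeta


@dataclass
class TrainResult:
    fold_models: list[ClassifierModel]
    predictions: pd.DataFrame  # subject_id, fold, label, yhat (out-of-sample)
    fold_assignment: dict[str, int]
    history: list[dict]


def train_classifier(
    model: ClassifierModel,
    cohort,
    folds: dict[str, int] | int = 5,
    epochs: int = 20,
    batch: int = 8,
    lr: float = 0.2,
    seed: int = 0,
    weight_decay: float = 0.0,
    augment: bool = True,
    augment_width: int | None = None,
    augment_prob: float = 0.5,
    augment_max_boxes: int = 1,
    restarts: int = 1,
) -> TrainResult:
    """Cross-validated training with per-fold out-of-sample predictions.

    For each test fold the next fold serves as validation set and the rest as
    training data; the epoch with the lowest validation loss is kept.  With
    ``restarts > 1``, several differently-initialized runs are trained per fold
    and the one with the best validation loss is selected (validation-based
    model selection, mirroring a small hyperparameter search).  Raises if any
    subject's volumes would span folds.
    """
    meta = pd.DataFrame([p.metadata() for p in cohort])
    if isinstance(folds, int):
        folds = make_stratified_folds(meta, k=folds, seed=seed)
    k = max(folds.values()) + 1
    fold_of = meta["subject_id"].map(folds)
    if fold_of.isna().any():
        raise ValueError("subjects missing from fold assignment")
    leak = meta.assign(fold=fold_of).groupby("subject_id")["fold"].nunique()
    if (leak > 1).any():
        raise ValueError("subject leakage: a subject spans multiple folds")

    x_all = np.stack([p.volume for p in cohort]).astype(np.float32)[:, None]
    y_all = meta["label"].to_numpy(dtype=np.float64)
    if augment_width is None:
        augment_width = max(3, (x_all.shape[-1] // 8) | 1)

    fold_models, history, pred_rows = [], [], []
    for f in range(k):
        test = np.flatnonzero(fold_of == f)
        val = np.flatnonzero(fold_of == (f + 1) % k) if k > 1 else test
        train = np.flatnonzero(~fold_of.isin([f, (f + 1) % k])) if k > 2 else (
            np.flatnonzero(fold_of != f) if k == 2 else test
        )
        if len(train) == 0:
            train = val
        best_model, best_loss = None, np.inf
        for r in range(max(restarts, 1)):
            m = build_model(
                **{k_: v for k_, v in model.config.items() if k_ != "seed"},
                seed=model.config.get("seed", 0) + 1000 * (f + 1) + 101 * r,
            ) if model.config else model.clone()
            rng = np.random.default_rng(seed + f + 7919 * r)
            best = (_bce(y_all[val], m.forward(x_all[val])) if epochs == 0
                    else np.inf, m.get_weights())
            for e in range(epochs):
                _sgd_epoch(m, x_all[train], y_all[train], batch, lr,
                           weight_decay, rng, augment, augment_width,
                           augment_prob, augment_max_boxes)
                val_loss = _bce(y_all[val], m.forward(x_all[val]))
                history.append({"fold": f, "restart": r, "epoch": e,
                                "val_loss": val_loss})
                if val_loss < best[0]:
                    best = (val_loss, m.get_weights())
            if epochs > 0:
                m.set_weights(best[1])
            if best[0] < best_loss or best_model is None:
                best_model, best_loss = m, best[0]
        m = best_model
        m.trained = epochs > 0
        m.fold_id = f
        fold_models.append(m)
        yhat = m.forward(x_all[test])
        for i, idx in enumerate(test):
            pred_rows.append(
                {"subject_id": meta.loc[idx, "subject_id"], "fold": f,
                 "label": int(y_all[idx]), "yhat": float(yhat[i])}
            )
    preds = pd.DataFrame(pred_rows)
    return TrainResult(fold_models=fold_models, predictions=preds,
                       fold_assignment=dict(folds), history=history)
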