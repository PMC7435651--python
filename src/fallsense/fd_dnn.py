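"""FD-DNN: a 1-D CNN + LSTM classifier for 2-s IMU windows.

The default architecture takes a (200 timesteps x 6 channels) window
through four SAME-padded stride-1 convolutions interleaved with
stride-2 max pooling (200 -> 100 -> 50 -> 25 -> 13 timesteps), reshapes
the pooled feature map into a 13-step sequence of 200-dimensional
vectors, runs it through two 200-unit LSTM layers with 0.5 dropout, and
classifies the final hidden state with an 8-way softmax layer.

Two distinct surfaces are exposed:

* a **framework-free auditor** (:func:`audit_shapes`,
  :func:`audit_params`) that computes every layer's output shape and
  trainable-parameter count from the declarative :class:`ModelSpec`
  alone — e.g. 608 parameters for the first convolution and 320,800 per
  200-unit LSTM layer;
* a **NumPy training engine** (:func:`train`, :func:`predict`) with
  hand-written backpropagation and Adam, used for end-to-end runs on
  synthetic data.  Gradients are verified against finite differences in
  the test suite.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

VALID_KINDS = {"conv1d", "maxpool1d", "reshape_split", "lstm", "dense"}
VALID_ACTIVATIONS = {"relu", "tanh", "softmax", None}


# ---------------------------------------------------------------------------
# Declarative architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    kind: str
    name: str = ""
    filters: int | None = None        # conv1d
    kernel: int | None = None         # conv1d: temporal extent
    stride: int = 1
    padding: str = "SAME"
    activation: str | None = None
    pool_size: int | None = None      # maxpool1d
    units: int | None = None          # lstm / dense
    dropout: float = 0.0              # lstm only
    forget_bias: float = 1.0          # lstm only

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.padding != "SAME":
            raise ValueError("only SAME padding is supported")
        if self.activation not in VALID_ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.kind == "conv1d" and (not self.filters or not self.kernel
                                      or self.filters < 1 or self.kernel < 1):
            raise ValueError("conv1d needs positive filters and kernel")
        if self.kind == "maxpool1d" and (not self.pool_size or self.pool_size < 1):
            raise ValueError("maxpool1d needs a positive pool size")
        if self.kind in ("lstm", "dense") and (not self.units or self.units < 1):
            raise ValueError(f"{self.kind} needs positive units")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    layers: tuple[LayerSpec, ...]
    input_length: int = 200
    in_channels: int = 6
    n_classes: int = 8

    def to_dict(self) -> dict:
        return {"input_length": self.input_length,
                "in_channels": self.in_channels,
                "n_classes": self.n_classes,
                "layers": [asdict(l) for l in self.layers]}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(layers=tuple(LayerSpec(**l) for l in d["layers"]),
                   input_length=d.get("input_length", 200),
                   in_channels=d.get("in_channels", 6),
                   n_classes=d.get("n_classes", 8))

    def to_yaml(self, path: str | Path | None = None) -> str:
        import yaml
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ModelSpec":
        import yaml
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


_CONV_PLAN = [(32, 3), (64, 5), (128, 7), (200, 9)]  # (filters, kernel) C1..C4


def default_model_spec(conv_layers: int = 4, lstm_units: int = 200,
                       input_length: int = 200, in_channels: int = 6,
                       n_classes: int = 8, dropout: float = 0.5) -> ModelSpec:
    """The standard architecture with ``conv_layers`` conv+pool blocks.

    Truncation keeps the first blocks of the C1..C4 plan; extension past
    four blocks replicates C4's 200-filter, 9-tap shape.  ``lstm_units``
    scales the recurrent width (200 in the full model; smaller values
    give the scaled-down variant used for quick end-to-end runs).
    """
    if not 1 <= conv_layers <= 6:
        raise ValueError("conv_layers must be between 1 and 6")
    plan = [_CONV_PLAN[min(i, 3)] for i in range(conv_layers)]
    layers: list[LayerSpec] = []
    for i, (f, k) in enumerate(plan, start=1):
        layers.append(LayerSpec(kind="conv1d", name=f"C{i}", filters=f,
                                kernel=k, stride=1, activation="relu"))
        layers.append(LayerSpec(kind="maxpool1d", name=f"S{i}", pool_size=2,
                                stride=2))
    layers.append(LayerSpec(kind="reshape_split", name="reshape"))
    for i in (1, 2):
        layers.append(LayerSpec(kind="lstm", name=f"L{i}", units=lstm_units,
                                dropout=dropout, forget_bias=1.0,
                                activation="tanh"))
    layers.append(LayerSpec(kind="dense", name="Fc", units=n_classes,
                            activation="softmax"))
    return ModelSpec(layers=tuple(layers), input_length=input_length,
                     in_channels=in_channels, n_classes=n_classes)


# ---------------------------------------------------------------------------
# Framework-free auditors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerAudit:
    name: str
    kind: str
    timesteps: int | None   # None once the temporal axis is consumed
    features: int
    params: int


def audit_model(spec: ModelSpec) -> list[LayerAudit]:
    """Walk the spec, deriving every layer's output shape and trainable
    parameter count by pure arithmetic.

    Conventions: SAME stride-1 convolution preserves length; SAME
    stride-2 pooling yields ceil(L/2); conv params =
    filters x (kernel x in_channels) + filters; LSTM params =
    4 x units x (input_dim + units + 1); dense params =
    units x input_dim + units; pooling and reshape contribute none.
    """
    rows = [LayerAudit("input", "input", spec.input_length, spec.in_channels, 0)]
    t: int | None = spec.input_length
    c = spec.in_channels
    for layer in spec.layers:
        if layer.kind == "conv1d":
            params = layer.filters * (layer.kernel * c) + layer.filters
            c = layer.filters
        elif layer.kind == "maxpool1d":
            if t is None:
                raise ValueError(f"{layer.name}: temporal axis already consumed")
            t = -(-t // (layer.stride or layer.pool_size))
            params = 0
        elif layer.kind == "reshape_split":
            params = 0
        elif layer.kind == "lstm":
            params = 4 * layer.units * (c + layer.units + 1)
            c = layer.units
        else:  # dense — consumes the temporal axis (last LSTM step)
            params = layer.units * c + layer.units
            c = layer.units
            t = None
        if layer.kind == "dense":
            rows.append(LayerAudit(layer.name, layer.kind, None, c, params))
        elif layer.kind == "lstm":
            rows.append(LayerAudit(layer.name, layer.kind, None, c, params))
        else:
            rows.append(LayerAudit(layer.name, layer.kind, t, c, params))
    return rows


def audit_shapes(spec: ModelSpec) -> list[tuple[str, int | None, int]]:
    """Per-layer (name, timesteps, features), input row included."""
    return [(r.name, r.timesteps, r.features) for r in audit_model(spec)]


def audit_params(spec: ModelSpec) -> dict[str, int]:
    """Per-layer trainable parameter counts plus a ``total`` entry."""
    rows = audit_model(spec)[1:]
    out = {r.name: r.params for r in rows}
    out["total"] = sum(r.params for r in rows)
    return out


def format_audit_table(spec: ModelSpec) -> str:
    lines = [f"{'layer':<10}{'kind':<15}{'output shape':<18}{'params':>12}"]
    total = 0
    for r in audit_model(spec):
        shape = f"({r.timesteps}, {r.features})" if r.timesteps is not None \
            else f"(-, {r.features})"
        lines.append(f"{r.name:<10}{r.kind:<15}{shape:<18}{r.params:>12,}")
        total += r.params
    lines.append(f"{'total':<10}{'':<15}{'':<18}{total:>12,}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Elementary functions
# ---------------------------------------------------------------------------

def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax: s_i = exp(x_i) / sum_j exp(x_j)."""
    x = np.asarray(x, dtype=float)
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def one_hot(labels: Sequence[int] | np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError(f"labels must lie in [0, {k})")
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray,
                  floor: float = 1e-12) -> float:
    """Mean categorical cross-entropy -1/n sum_i y'_i log(y_i), with the
    log argument clamped at ``floor``."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    return float(-np.mean(np.sum(y_true * np.log(np.maximum(y_pred, floor)),
                                 axis=1)))


# ---------------------------------------------------------------------------
# NumPy layers with hand-written backpropagation
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class _Conv1D:
    """SAME-padded stride-1 temporal convolution spanning all channels."""

    def __init__(self, spec: LayerSpec, in_channels: int,
                 rng: np.random.Generator) -> None:
        k, f = spec.kernel, spec.filters
        self.k, self.f, self.cin = k, f, in_channels
        self.relu = spec.activation == "relu"
        self.W = _glorot(rng, (k * in_channels, f), k * in_channels, f)
        self.b = np.zeros(f)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, t, c = x.shape
        left = (self.k - 1) // 2
        right = self.k - 1 - left
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # (b, t, c, k) -> (b, t, k, c) -> (b, t, k*c)
        return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(b, t, -1)

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator) -> np.ndarray:
        self.col = self._im2col(x)
        self.in_shape = x.shape
        z = self.col @ self.W + self.b
        if self.relu:
            self.mask = z > 0
            z = z * self.mask
        return z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * self.mask
        b, t, _ = dy.shape
        self.grads[0][...] = np.tensordot(self.col, dy, axes=([0, 1], [0, 1]))
        self.grads[1][...] = dy.sum(axis=(0, 1))
        dcol = (dy @ self.W.T).reshape(b, t, self.k, self.cin)
        left = (self.k - 1) // 2
        _, tin, _ = self.in_shape
        dxp = np.zeros((b, tin + self.k - 1, self.cin))
        for j in range(self.k):
            dxp[:, j:j + t] += dcol[:, :, j]
        return dxp[:, left:left + tin]


class _MaxPool1D:
    """SAME pool of size 2, stride 2: output length ceil(T/2)."""

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator) -> np.ndarray:
        b, t, c = x.shape
        self.t_in = t
        if t % 2:
            x = np.concatenate([x, np.full((b, 1, c), -np.inf)], axis=1)
        pairs = x.reshape(b, -1, 2, c)
        self.arg = pairs.argmax(axis=2)
        return pairs.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, t_out, c = dy.shape
        dx = np.zeros((b, t_out, 2, c))
        bi, ti, ci = np.meshgrid(np.arange(b), np.arange(t_out),
                                 np.arange(c), indexing="ij")
        dx[bi, ti, self.arg, ci] = dy
        return dx.reshape(b, 2 * t_out, c)[:, :self.t_in]


class _Reshape:
    """Marker for the pooled-map-to-sequence handoff; the (batch,
    timesteps, features) layout is already the recurrent layout."""

    def forward(self, x, train, rng):
        return x

    def backward(self, dy):
        return dy


class _LSTM:
    """Single LSTM layer, full backpropagation through time.

    One fused weight matrix W of shape (input + units, 4*units) with gate
    order (input, forget, candidate, output) and a bias of 4*units values
    whose forget section initializes to ``forget_bias``; total trainable
    parameters 4*units*(input + units + 1).  States start at zero for
    every sequence.  Inverted dropout on the output sequence during
    training only.
    """

    def __init__(self, spec: LayerSpec, in_dim: int,
                 rng: np.random.Generator) -> None:
        h = spec.units
        self.h, self.d = h, in_dim
        self.dropout = spec.dropout
        self.W = _glorot(rng, (in_dim + h, 4 * h), in_dim + h, 4 * h)
        self.b = np.zeros(4 * h)
        self.b[h:2 * h] = spec.forget_bias
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator) -> np.ndarray:
        b, t, _ = x.shape
        h = self.h
        self.x = x
        self.cache = []
        h_t = np.zeros((b, h))
        c_t = np.zeros((b, h))
        out = np.empty((b, t, h))
        for s in range(t):
            zin = np.concatenate([x[:, s], h_t], axis=1)
            z = zin @ self.W + self.b
            i = self._sigmoid(z[:, :h])
            f = self._sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = self._sigmoid(z[:, 3 * h:])
            c_t = f * c_t + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            self.cache.append((zin, i, f, g, o, c_t, tc))
            out[:, s] = h_t
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            self.drop_mask = (rng.random(out.shape) < keep) / keep
            out = out * self.drop_mask
        else:
            self.drop_mask = None
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.drop_mask is not None:
            dy = dy * self.drop_mask
        b, t, _ = dy.shape
        h, d = self.h, self.d
        dW = self.grads[0]
        db = self.grads[1]
        dW[...] = 0.0
        db[...] = 0.0
        dx = np.zeros_like(self.x)
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        for s in range(t - 1, -1, -1):
            zin, i, f, g, o, c_t, tc = self.cache[s]
            c_prev = self.cache[s - 1][5] if s > 0 else np.zeros((b, h))
            dh = dy[:, s] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g**2), do * o * (1 - o)], axis=1)
            dW += zin.T @ dz
            db += dz.sum(axis=0)
            dzin = dz @ self.W.T
            dx[:, s] = dzin[:, :d]
            dh_next = dzin[:, d:]
        return dx


class _TakeLast:
    """Select the final LSTM step as the sequence summary."""

    def forward(self, x, train, rng):
        self.t = x.shape[1]
        return x[:, -1]

    def backward(self, dy):
        dx = np.zeros((dy.shape[0], self.t, dy.shape[1]))
        dx[:, -1] = dy
        return dx


class _Dense:
    """Fully connected output layer; softmax is applied by the caller."""

    def __init__(self, spec: LayerSpec, in_dim: int,
                 rng: np.random.Generator) -> None:
        self.W = _glorot(rng, (in_dim, spec.units), in_dim, spec.units)
        self.b = np.zeros(spec.units)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self.x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self.x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


def build_network(spec: ModelSpec, rng: np.random.Generator) -> list:
    """Instantiate NumPy layers from a ModelSpec (shape-checked)."""
    layers: list = []
    c = spec.in_channels
    for layer in spec.layers:
        if layer.kind == "conv1d":
            layers.append(_Conv1D(layer, c, rng))
            c = layer.filters
        elif layer.kind == "maxpool1d":
            layers.append(_MaxPool1D())
        elif layer.kind == "reshape_split":
            layers.append(_Reshape())
        elif layer.kind == "lstm":
            layers.append(_LSTM(layer, c, rng))
            c = layer.units
        else:
            layers.append(_TakeLast())
            layers.append(_Dense(layer, c, rng))
            c = layer.units
    return layers


def _forward(layers: list, x: np.ndarray, train: bool,
             rng: np.random.Generator) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, train, rng)
    return x


def _backward(layers: list, dy: np.ndarray) -> None:
    for layer in reversed(layers):
        dy = layer.backward(dy)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, eps: float,
                 beta1: float = 0.9, beta2: float = 0.999) -> None:
        self.params = params
        self.lr, self.eps, self.b1, self.b2 = lr, eps, beta1, beta2
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# Training harness
# ---------------------------------------------------------------------------

class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: Adam mini-batch optimization with periodic
    metric logging, checkpointing, and plateau-based early stopping.

    ``dropout`` overrides the LSTM layers' own dropout when set;
    cadences are in iterations (mini-batches)."""

    batch_size: int = 128
    learning_rate: float = 1e-3
    epsilon: float = 1e-8
    max_epochs: int = 300
    dropout: float | None = None
    train_metric_every: int = 5
    val_every: int = 25
    checkpoint_every_epochs: int = 10
    patience: int = 20
    min_delta: float = 1e-4
    restore_best: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "learning_rate", "epsilon", "max_epochs",
                     "train_metric_every", "val_every",
                     "checkpoint_every_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedModel:
    spec: ModelSpec
    layers: list
    config: TrainConfig
    history: list[dict] = field(default_factory=list)
    stopped_epoch: int | None = None

    def export_history_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["iteration", "epoch", "split", "loss",
                                "accuracy"])
            writer.writeheader()
            writer.writerows(self.history)

    def save_checkpoint(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(getattr(layer, "params", [])):
                arrays[f"layer{i}_param{j}"] = p
        np.savez(path, **arrays)

    def load_checkpoint(self, path: str | Path) -> None:
        with np.load(path) as data:
            for i, layer in enumerate(self.layers):
                for j, p in enumerate(getattr(layer, "params", [])):
                    p[...] = data[f"layer{i}_param{j}"]


def _accuracy(probs: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(probs.argmax(axis=1) == labels))


def train(spec: ModelSpec, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          config: TrainConfig | None = None,
          checkpoint_dir: str | Path | None = None) -> TrainedModel:
    """Fully supervised mini-batch training with Adam.

    Dropout is active only during training; LSTM states start at zero
    for every window; history rows are recorded every
    ``train_metric_every`` iterations (current batch) and every
    ``val_every`` iterations (full validation set).  Early stopping
    monitors validation accuracy with the configured patience, counted
    in validation checks.
    """
    config = config or TrainConfig()
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(x_train) == 0:
        raise TrainingError("empty training set")
    if x_train.shape[1:] != (spec.input_length, spec.in_channels):
        raise ValueError(
            f"window shape {x_train.shape[1:]} does not match spec "
            f"({spec.input_length}, {spec.in_channels})")
    if config.dropout is not None:
        spec = ModelSpec(
            layers=tuple(
                LayerSpec(**{**asdict(l), "dropout": config.dropout})
                if l.kind == "lstm" else l for l in spec.layers),
            input_length=spec.input_length, in_channels=spec.in_channels,
            n_classes=spec.n_classes)

    rng = np.random.default_rng(config.seed)
    layers = build_network(spec, rng)
    model = TrainedModel(spec=spec, layers=layers, config=config)
    params = [p for l in layers for p in getattr(l, "params", [])]
    grads = [g for l in layers for g in getattr(l, "grads", [])]
    opt = _Adam(params, config.learning_rate, config.epsilon)
    y_onehot = one_hot(y_train, spec.n_classes)

    iteration = 0
    best_val = -np.inf
    best_params: list[np.ndarray] | None = None
    stale_checks = 0
    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x_train))
        stop = False
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_train[idx], y_onehot[idx]
            logits = _forward(layers, xb, train=True, rng=rng)
            probs = softmax(logits)
            loss = cross_entropy(yb, probs)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss {loss} at iteration {iteration} "
                    f"(epoch {epoch}); reduce the learning rate")
            _backward(layers, (probs - yb) / len(xb))
            opt.step(grads)
            iteration += 1
            if iteration % config.train_metric_every == 0:
                model.history.append({
                    "iteration": iteration, "epoch": epoch, "split": "train",
                    "loss": loss, "accuracy": _accuracy(probs, y_train[idx])})
            if (x_val is not None and len(x_val)
                    and iteration % config.val_every == 0):
                vprobs, _ = predict(model, x_val)
                vloss = cross_entropy(one_hot(np.asarray(y_val, int),
                                              spec.n_classes), vprobs)
                vacc = _accuracy(vprobs, np.asarray(y_val, int))
                model.history.append({
                    "iteration": iteration, "epoch": epoch, "split": "val",
                    "loss": vloss, "accuracy": vacc})
                if vacc > best_val + config.min_delta:
                    best_val = vacc
                    if config.restore_best:
                        best_params = [p.copy() for p in params]
                    stale_checks = 0
                else:
                    stale_checks += 1
                    if stale_checks >= config.patience:
                        stop = True
                        break
        if ckpt_dir and epoch % config.checkpoint_every_epochs == 0:
            model.save_checkpoint(ckpt_dir / f"epoch_{epoch:04d}.npz")
        if stop:
            model.stopped_epoch = epoch
            break
    if best_params is not None:
        # guard against late optimization instability: hand back the
        # weights of the best validation check, not the last batch's
        for p, bp in zip(params, best_params):
            p[...] = bp
    return model


def predict(model: TrainedModel, windows: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties -> lowest index).
    Dropout is disabled, so prediction is deterministic."""
    windows = np.asarray(windows, dtype=float)
    if windows.shape[1:] != (model.spec.input_length, model.spec.in_channels):
        raise ValueError(
            f"window shape {windows.shape[1:]} does not match model "
            f"({model.spec.input_length}, {model.spec.in_channels})")
    rng = np.random.default_rng(0)  # unused when train=False
    probs = softmax(_forward(model.layers, windows, train=False, rng=rng))
    return probs, probs.argmax(axis=1)
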