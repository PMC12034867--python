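"""One-dimensional convolutional classifier for velocity envelopes.

Architecture: conv(32) -> ReLU -> maxpool(2) -> conv(64) -> ReLU -> maxpool(2)
-> conv(128) -> ReLU -> maxpool(2) -> flatten -> dense(128) -> ReLU ->
dense(2) -> softmax. Convolutions are stride-1 with length-preserving (same)
padding; pooling is non-overlapping with window 2. For the 1000-sample input
grid the pooled lengths are 500, 250, 125 and the flattened feature vector
has 125 x 128 = 16000 entries.

The network, its backward pass, and the Adam optimizer are implemented
directly on NumPy arrays. Convolutions are expressed as a single BLAS matmul
over sliding windows, which is fast enough to train the study-sized problem
(a few hundred signals) on one CPU core. Weight initialization is He
(fan-in-scaled normal) for all hidden layers and zero for the classifier
head, so an untrained model emits uniform class probabilities — exactly
uninformative before the first optimizer step. Initialization and the
shuffling schedule are fully determined by the training seed, so a fixed
seed reproduces weights bit-for-bit on one worker.

Input normalization: per-signal standardization (subtract the signal mean,
divide by its SD) is the default, keeping activations near unit magnitude
for the optimizer; ``"scale"`` (divide by a fixed 100 cm/s) preserves
absolute velocity information, and ``"none"`` feeds the raw extracted
velocities, reproducing training on the bare signals literally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, DataError, NumericalFailureError

NORMALIZATIONS = ("none", "scale", "zscore")


@dataclass(frozen=True)
class CNNConfig:
    """Architecture constants of the three-block 1-D CNN."""

    conv_channels: tuple[int, int, int] = (32, 64, 128)
    kernel_size: int = 3
    pool_size: int = 2
    hidden_units: int = 128
    n_classes: int = 2
    normalization: str = "zscore"
    norm_scale: float = 100.0  # cm/s

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3 or any(c < 1 for c in self.conv_channels):
            raise ConfigurationError("conv_channels must be three positive integers")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ConfigurationError("kernel_size must be a positive odd integer")
        if self.pool_size < 2:
            raise ConfigurationError("pool_size must be >= 2")
        if self.hidden_units < 1 or self.n_classes < 2:
            raise ConfigurationError("hidden_units >= 1 and n_classes >= 2 required")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigurationError(f"normalization must be one of {NORMALIZATIONS}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam + cross-entropy)."""

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 500
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Conv1d:
    """Stride-1 same-padding 1-D convolution via an im2col matmul."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.c_in, self.c_out, self.k = c_in, c_out, k

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, C_in, L)
        n, _, length = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.k, axis=2)  # (N, C_in, L, K)
        a = win.transpose(0, 2, 1, 3).reshape(n * length, self.c_in * self.k)
        self._a = a
        self._shape = (n, length)
        w2 = self.W.reshape(self.c_out, -1).T
        y = (a @ w2).reshape(n, length, self.c_out).transpose(0, 2, 1)
        return y + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length = self._shape
        g = dy.transpose(0, 2, 1).reshape(n * length, self.c_out)
        self.dW = (self._a.T @ g).T.reshape(self.c_out, self.c_in, self.k)
        self.db = g.sum(axis=0)
        da = (g @ self.W.reshape(self.c_out, -1)).reshape(n, length, self.c_in, self.k)
        p = self.k // 2
        dxp = np.zeros((n, self.c_in, length + 2 * p))
        for kk in range(self.k):
            dxp[:, :, kk : kk + length] += da[:, :, :, kk].transpose(0, 2, 1)
        return dxp[:, :, p : p + length]

    def grads(self):
        return [self.dW, self.db]


class _MaxPool1d:
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, size: int):
        self.size = size

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        lo = length // self.size
        xt = x[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        self._idx = xt.argmax(axis=3)
        self._shape = (n, c, length, lo)
        return xt.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length, lo = self._shape
        dx = np.zeros((n, c, lo, self.size))
        np.put_along_axis(dx, self._idx[..., None], dy[..., None], axis=3)
        out = np.zeros((n, c, length))
        out[:, :, : lo * self.size] = dx.reshape(n, c, lo * self.size)
        return out

    def grads(self):
        return []


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)

    def grads(self):
        return []


class _Flatten:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    def grads(self):
        return []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def grads(self):
        return [self.dW, self.db]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class CNN1D:
    """The three-block convolutional classifier (untrained or trained)."""

    def __init__(self, config: CNNConfig, input_length: int = 1000, seed: int = 0):
        min_len = 8 * config.pool_size**3
        if input_length < min_len:
            raise ConfigurationError(
                f"input_length {input_length} too short for three poolings "
                f"(need >= {min_len})"
            )
        self.config = config
        self.input_length = input_length
        self.seed = seed
        rng = np.random.default_rng(seed)
        c1, c2, c3 = config.conv_channels
        k, p = config.kernel_size, config.pool_size
        l1 = input_length // p
        l2 = l1 // p
        l3 = l2 // p
        self.flat_size = l3 * c3
        self.layers = [
            _Conv1d(1, c1, k, rng),
            _ReLU(),
            _MaxPool1d(p),
            _Conv1d(c1, c2, k, rng),
            _ReLU(),
            _MaxPool1d(p),
            _Conv1d(c2, c3, k, rng),
            _ReLU(),
            _MaxPool1d(p),
            _Flatten(),
            _Dense(self.flat_size, config.hidden_units, rng),
            _ReLU(),
            _Dense(config.hidden_units, config.n_classes, rng),
        ]
        # zero-init the classifier head: an untrained network emits uniform
        # class probabilities (carries no class information before training);
        # the head receives a nonzero gradient at the first step, so training
        # dynamics are unaffected
        self.layers[-1].W[...] = 0.0

    # -- parameter access ---------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [arr for layer in self.layers for _, arr in layer.params()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params():
                out[f"layer{i:02d}_{name}"] = arr
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params():
                arr[...] = arrays[f"layer{i:02d}_{name}"]

    # -- inference ----------------------------------------------------------

    def _normalize(self, signals: np.ndarray) -> np.ndarray:
        x = np.asarray(signals, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.input_length:
            raise DataError(
                f"signals must be (n, {self.input_length}), got {x.shape}"
            )
        mode = self.config.normalization
        if mode == "scale":
            return x / self.config.norm_scale
        if mode == "zscore":
            mu = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, keepdims=True)
            return (x - mu) / np.where(sd > 0, sd, 1.0)
        return x

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x[:, None, :]
        for layer in self.layers:
            h = layer.forward(h)
        return h  # logits (n, n_classes)

    def predict_proba(self, signals: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class-probability matrix (n, n_classes); column 1 is ARAS."""
        x = self._normalize(signals)
        out = [
            _softmax(self._forward(x[i : i + batch_size]))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, signals: np.ndarray) -> np.ndarray:
        """Predicted binary labels (argmax of the softmax)."""
        return self.predict_proba(signals).argmax(axis=1)


@dataclass
class TrainedModel:
    """A trained network plus its full training provenance."""

    model: CNN1D
    train_config: TrainConfig
    training_log: list[float] = field(default_factory=list)  # mean loss per epoch
    n_steps: int = 0

    @property
    def config(self) -> CNNConfig:
        return self.model.config

    def predict_proba(self, signals: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(signals)

    def predict(self, signals: np.ndarray) -> np.ndarray:
        return self.model.predict(signals)

    def score_positive(self, signals: np.ndarray) -> np.ndarray:
        """P(ARAS) per signal — the score used for ROC analysis."""
        return self.model.predict_proba(signals)[:, 1]

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights + configs + seed (npz, schema v1)."""
        meta = {
            "schema": 1,
            "cnn_config": asdict(self.config),
            "train_config": asdict(self.train_config),
            "input_length": self.model.input_length,
            "seed": self.model.seed,
            "n_steps": self.n_steps,
            "training_log": self.training_log,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.model.state_arrays(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("schema") != 1:
                raise DataError(f"unsupported checkpoint schema {meta.get('schema')}")
            ccfg = meta["cnn_config"]
            ccfg["conv_channels"] = tuple(ccfg["conv_channels"])
            cnn_cfg = CNNConfig(**ccfg)
            model = CNN1D(cnn_cfg, input_length=meta["input_length"], seed=meta["seed"])
            model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
        out = cls(
            model=model,
            train_config=TrainConfig(**meta["train_config"]),
            training_log=list(meta["training_log"]),
            n_steps=int(meta["n_steps"]),
        )
        return out


def build_model(cfg: CNNConfig | None = None, input_length: int = 1000, seed: int = 0) -> CNN1D:
    """Construct an untrained network with seed-reproducible initialization."""
    return CNN1D(cfg or CNNConfig(), input_length=input_length, seed=seed)


class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            mhat = m / (1 - c.beta1**self.t)
            vhat = v / (1 - c.beta2**self.t)
            p -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)


def train(
    model: CNN1D,
    signals: np.ndarray,
    labels: np.ndarray,
    tcfg: TrainConfig | None = None,
) -> TrainedModel:
    """Train with Adam on mean-reduced cross-entropy.

    The per-epoch shuffling schedule and the weight initialization both
    derive from ``tcfg.seed``, so a fixed seed reproduces the final weights
    exactly on one worker. The final partial batch of each epoch is kept.

    Raises :class:`DataError` if only one class is present and
    :class:`NumericalFailureError` (with the epoch index) if the loss goes
    non-finite.
    """
    tcfg = tcfg or TrainConfig()
    y = np.asarray(labels).astype(int)
    x = model._normalize(signals)
    if x.shape[0] != y.shape[0]:
        raise DataError("signals and labels length mismatch")
    classes = np.unique(y)
    if classes.size < 2:
        raise DataError("training set contains a single class")
    if classes.min() < 0 or classes.max() >= model.config.n_classes:
        raise DataError("labels outside the model's class range")

    rng = np.random.default_rng(tcfg.seed)
    opt = _Adam(model.parameters(), tcfg)
    n = x.shape[0]
    log: list[float] = []
    steps = 0
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model._forward(xb)
            probs = _softmax(logits)
            eps = 1e-12
            loss = float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + eps)))
            if not np.isfinite(loss):
                raise NumericalFailureError(f"non-finite loss at epoch {epoch + 1}")
            losses.append(loss)
            dz = probs.copy()
            dz[np.arange(len(yb)), yb] -= 1.0
            dz /= len(yb)
            grad = dz
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            opt.step([g for layer in model.layers for g in layer.grads()])
            steps += 1
        log.append(float(np.mean(losses)))
    return TrainedModel(model=model, train_config=tcfg, training_log=log, n_steps=steps)


def fit(
    signals: np.ndarray,
    labels: np.ndarray,
    cnn_cfg: CNNConfig | None = None,
    tcfg: TrainConfig | None = None,
    input_length: int = 1000,
) -> TrainedModel:
    """Build (seeded from the train config) and train in one call."""
    tcfg = tcfg or TrainConfig()
    model = build_model(cnn_cfg, input_length=input_length, seed=tcfg.seed)
    return train(model, signals, labels, tcfg)
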