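"""The convolutional regression network and its training loop.

Architecture (four layers: input, convolution, hidden dense, output dense):

* Input: per-bin ``N x 2`` matrix ``s``; ``s[i, 0]`` the i-th feature's
  scaled value in the bin, ``s[i, 1]`` the scaled mean over nearby bins.
* Convolution: 64 width-2 filters shared across features,
  ``X[f, i] = ReLU(sum_k w[f, k] * s[i, k])`` — the filter weights carry no
  feature index, so every feature row is transformed identically.
* The ``N x 64`` map is flattened feature-major (row i contributes entries
  ``64*i .. 64*i+63`` of ``Y``), then ``Z = ReLU(W2 @ Y + b2)`` with 256
  hidden units, and the output ``C_hat = ReLU(W3 @ Z + b3)`` is a single
  non-negative predicted methylation level.

Training minimizes the mean squared error ``F = (1/V) sum_v (C_v -
C_hat_v)^2`` with minibatch Adam (batch size 100 by default), monitoring F
on a validation set after every epoch and stopping once F has not improved
for ``patience_epochs`` consecutive epochs; the best-epoch weights are
restored. All randomness (initialization, shuffling) derives from the seed
in :class:`ModelSpec`, so runs are bit-reproducible within one build.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "ModelState",
    "TrainingLog",
    "EarlyStopping",
    "forward",
    "train",
    "predict",
    "mse",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyperparameters."""

    n_features: int
    n_filters: int = 64
    kernel_width: int = 2
    hidden_dim: int = 256
    batch_size: int = 100
    patience_epochs: int = 20
    max_epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        for name in ("n_filters", "kernel_width", "hidden_dim", "batch_size",
                     "patience_epochs", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModelState:
    """Learned weights; shapes fixed by the spec.

    ``w``: (n_filters, kernel_width) shared conv filters. ``W2``:
    (hidden_dim, n_filters * n_features), ``b2``: (hidden_dim,). ``W3``:
    (1, hidden_dim), ``b3``: (1,).
    """

    spec: ModelSpec
    w: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def params(self) -> list[np.ndarray]:
        return [self.w, self.W2, self.b2, self.W3, self.b3]

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_params(self, params: Sequence[np.ndarray]) -> None:
        self.w, self.W2, self.b2, self.W3, self.b3 = [p.copy() for p in params]

    def validate(self) -> None:
        s = self.spec
        expected = {
            "w": (s.n_filters, s.kernel_width),
            "W2": (s.hidden_dim, s.n_filters * s.n_features),
            "b2": (s.hidden_dim,),
            "W3": (1, s.hidden_dim),
            "b3": (1,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")


@dataclass
class TrainingLog:
    """Per-epoch losses and the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def best_val_loss(self) -> float:
        return min(self.val_loss) if self.val_loss else float("nan")

    @property
    def epochs_run(self) -> int:
        return len(self.val_loss)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_state(spec: ModelSpec, feature_names: Sequence[str] | None = None) -> ModelState:
    """Glorot-uniform weights, seeded by ``spec.seed``.

    Biases start at zero except the output bias, which starts at 0.1: with a
    ReLU output head a non-positive initial pre-activation for every input
    zeroes the loss gradient (a dead network), and the small positive offset
    makes that failure mode vanishingly unlikely without affecting the
    converged fit.
    """
    rng = np.random.default_rng(spec.seed)
    state = ModelState(
        spec=spec,
        w=_glorot(rng, spec.kernel_width, spec.n_filters,
                  (spec.n_filters, spec.kernel_width)),
        W2=_glorot(rng, spec.n_filters * spec.n_features, spec.hidden_dim,
                   (spec.hidden_dim, spec.n_filters * spec.n_features)),
        b2=np.zeros(spec.hidden_dim),
        W3=_glorot(rng, spec.hidden_dim, 1, (1, spec.hidden_dim)),
        b3=np.full(1, 0.1),
        feature_names=tuple(feature_names) if feature_names else None,
    )
    state.validate()
    return state


def _as_batch(s: np.ndarray, spec: ModelSpec) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.ndim == 2:
        s = s[None, :, :]
    if s.ndim != 3 or s.shape[1] != spec.n_features or s.shape[2] != spec.kernel_width:
        raise ValueError(
            f"input shape {s.shape} incompatible with "
            f"(n, {spec.n_features}, {spec.kernel_width})"
        )
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite values in input")
    return s


def _forward_cache(state: ModelState, s: np.ndarray):
    """Vectorized forward pass keeping pre-activations for backprop."""
    B, N, _ = s.shape
    A1 = np.einsum("bnk,fk->bnf", s, state.w)  # (B, N, F)
    X = np.maximum(A1, 0.0)
    Y = X.reshape(B, N * state.spec.n_filters)  # feature-major flatten
    A2 = Y @ state.W2.T + state.b2
    Z = np.maximum(A2, 0.0)
    A3 = Z @ state.W3.T + state.b3  # (B, 1)
    C = np.maximum(A3, 0.0)
    return C[:, 0], (s, A1, Y, A2, Z, A3)


def forward(state: ModelState, s: np.ndarray) -> np.ndarray | float:
    """Predict methylation for one bin (N x 2) or a batch (B x N x 2).

    Returns a scalar for a single bin, else a length-B vector; always >= 0
    because of the final ReLU.
    """
    single = np.asarray(s).ndim == 2
    batch = _as_batch(s, state.spec)
    out, _ = _forward_cache(state, batch)
    return float(out[0]) if single else out


def _backward(state: ModelState, cache, targets: np.ndarray):
    """Gradients of the batch MSE w.r.t. all parameters."""
    s, A1, Y, A2, Z, A3 = cache
    B = s.shape[0]
    C = np.maximum(A3[:, 0], 0.0)
    dC = 2.0 * (C - targets) / B  # (B,)
    d3 = (dC * (A3[:, 0] > 0))[:, None]  # (B, 1)
    gW3 = d3.T @ Z
    gb3 = d3.sum(axis=0)
    dZ = d3 @ state.W3  # (B, H)
    d2 = dZ * (A2 > 0)
    gW2 = d2.T @ Y
    gb2 = d2.sum(axis=0)
    dY = d2 @ state.W2  # (B, N*F)
    dX = dY.reshape(A1.shape) * (A1 > 0)  # (B, N, F)
    gw = np.einsum("bnf,bnk->fk", dX, s)
    return [gw, gW2, gb2, gW3, gb3]


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class EarlyStopping:
    """Stop when the monitored loss has not improved for ``patience``
    consecutive epochs; remembers the best epoch and its weight snapshot.

    ``update`` returns True when training should stop. Improvement means a
    strictly smaller loss than the best seen so far.
    """

    def __init__(self, patience: int):
        if patience <= 0:
            raise ValueError("patience must be positive")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = -1
        self.best_params: list[np.ndarray] | None = None
        self.epochs_since_best = 0

    def update(self, epoch: int, loss: float,
               params: Sequence[np.ndarray] | None = None) -> bool:
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
            self.epochs_since_best = 0
            if params is not None:
                self.best_params = [p.copy() for p in params]
        else:
            self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience


def mse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared error F over bins."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError(f"length mismatch: {actual.shape} vs {predicted.shape}")
    if actual.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean((actual - predicted) ** 2))


def train(
    spec: ModelSpec,
    train_matrix: np.ndarray,
    train_targets: np.ndarray,
    val_matrix: np.ndarray,
    val_targets: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> tuple[ModelState, TrainingLog]:
    """Fit the network by minibatch Adam with early stopping on validation F.

    Returns the state restored to the best-validation epoch and the full
    per-epoch log. Deterministic for a given spec (seed included).
    """
    train_matrix = _as_batch(np.asarray(train_matrix), spec)
    val_matrix = _as_batch(np.asarray(val_matrix), spec)
    train_targets = np.asarray(train_targets, dtype=float)
    val_targets = np.asarray(val_targets, dtype=float)
    if train_matrix.shape[0] == 0:
        raise ValueError("empty training set")
    if val_matrix.shape[0] == 0:
        raise ValueError("empty validation set")
    if train_matrix.shape[0] != train_targets.shape[0]:
        raise ValueError("training matrix/target length mismatch")

    state = init_state(spec, feature_names)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    optimizer = _Adam(state.params(), lr=spec.learning_rate)
    stopper = EarlyStopping(spec.patience_epochs)
    log = TrainingLog()

    n = train_matrix.shape[0]
    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, spec.batch_size):
            idx = order[lo:lo + spec.batch_size]
            preds, cache = _forward_cache(state, train_matrix[idx])
            epoch_losses.append(mse(train_targets[idx], preds))
            grads = _backward(state, cache, train_targets[idx])
            optimizer.step(state.params(), grads)
        val_preds, _ = _forward_cache(state, val_matrix)
        F = mse(val_targets, val_preds)
        log.train_loss.append(float(np.mean(epoch_losses)))
        log.val_loss.append(F)
        if stopper.update(epoch, F, state.params()):
            log.stop_reason = "early_stopping"
            break
    else:
        log.stop_reason = "max_epochs"
    log.best_epoch = stopper.best_epoch
    if stopper.best_params is not None:
        state.set_params(stopper.best_params)
    return state, log


def predict(
    state: ModelState,
    matrix,
    feature_names: Sequence[str] | None = None,
    clip: bool = False,
    batch_size: int = 4096,
) -> np.ndarray:
    """Per-bin predictions; raw non-negative by default, clipped to [0, 1]
    with ``clip=True``. Accepts a (B, N, 2) array or a
    :class:`epinet.binning.FeatureMatrix` (whose feature order is checked
    against the model's).
    """
    names = feature_names
    if hasattr(matrix, "data") and hasattr(matrix, "feature_names"):
        names = matrix.feature_names
        matrix = matrix.data
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] == 0:
        return np.empty(0)
    if state.feature_names is not None and names is not None:
        if tuple(names) != tuple(state.feature_names):
            raise ValueError(
                f"feature order mismatch: model expects {state.feature_names}, "
                f"got {tuple(names)}"
            )
    matrix = _as_batch(matrix, state.spec)
    chunks = []
    for lo in range(0, matrix.shape[0], batch_size):
        out, _ = _forward_cache(state, matrix[lo:lo + batch_size])
        chunks.append(out)
    preds = np.concatenate(chunks)
    return np.clip(preds, 0.0, 1.0) if clip else preds


def save_model(state: ModelState, path: str | Path) -> None:
    """Serialize spec + weights to one portable ``.npz`` file."""
    meta = {
        "spec": asdict(state.spec),
        "feature_names": list(state.feature_names) if state.feature_names else None,
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        w=state.w, W2=state.W2, b2=state.b2, W3=state.W3, b3=state.b3,
    )


def load_model(path: str | Path, expect_features: Sequence[str] | None = None) -> ModelState:
    """Load a saved model; refuses a feature list that does not match."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec = ModelSpec(**meta["spec"])
        names = tuple(meta["feature_names"]) if meta["feature_names"] else None
        state = ModelState(
            spec=spec,
            w=data["w"], W2=data["W2"], b2=data["b2"],
            W3=data["W3"], b3=data["b3"],
            feature_names=names,
        )
    state.validate()
    if expect_features is not None and names is not None:
        if tuple(expect_features) != names:
            raise ValueError(
                f"model was trained on features {names}, caller expects "
                f"{tuple(expect_features)}"
            )
    return state
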