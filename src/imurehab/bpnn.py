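"""From-scratch back-propagation network with validation early stopping.

The recognizer is a fixed-architecture feed-forward network: 800 inputs,
5 log-sigmoid hidden neurons, 6 linear outputs.  Training is full-batch
gradient descent on the mean squared error, stopping when the training MSE
reaches the performance goal (PG), when the validation MSE has risen for a
configured number of consecutive epochs (weights restored to the best
validation epoch), or at the epoch budget.  Sizes are configurable so that
miniature networks can be checked by hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import INPUT_LENGTH, N_EXERCISES, FeatureScaler, stack_cells

DEFAULT_SIZES = (INPUT_LENGTH, 5, N_EXERCISES)

__all__ = [
    "DEFAULT_SIZES",
    "TrainingConfig",
    "NetworkModel",
    "logsig",
    "forward",
    "train",
    "evaluate_mse",
    "stratified_split",
]


def logsig(t):
    """Logistic sigmoid ``1 / (1 + exp(-t))``, stable for large ``|t|``."""
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of one training run.

    ``pg`` is the target training MSE; ``patience`` the number of
    consecutive epochs of rising validation MSE tolerated before stopping
    (1 stops at the first rise).
    """

    pg: float = 1e-5
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    learning_rate: float = 0.5
    momentum: float = 0.9
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    max_error_increase: float = 1.04
    max_epochs: int = 5000
    patience: int = 30
    restarts: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.pg <= 0:
            raise ValueError("performance goal must be positive")
        if any(f <= 0 for f in self.split) or abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")
        if self.patience < 1 or self.max_epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")
        if self.lr_increase < 1.0 or not 0 < self.lr_decrease <= 1.0 or self.restarts < 0:
            raise ValueError("invalid training configuration")

    def to_dict(self) -> dict:
        return {
            "pg": self.pg,
            "split": list(self.split),
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
            "lr_increase": self.lr_increase,
            "lr_decrease": self.lr_decrease,
            "max_error_increase": self.max_error_increase,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "restarts": self.restarts,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        d["split"] = tuple(d["split"])
        return cls(**d)


@dataclass
class NetworkModel:
    """Weights, scaling and training history of a trained network."""

    sizes: tuple[int, int, int]
    w_hidden: np.ndarray  # (l, n)
    b_hidden: np.ndarray  # (l,)
    w_out: np.ndarray  # (m, l)
    b_out: np.ndarray  # (m,)
    scaler: FeatureScaler | None = None
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    test_mse: float | None = None
    pg_reached: bool = False
    stop_reason: str = "untrained"
    config: TrainingConfig | None = None
    split_indices: dict | None = None  # {"train": [...], "val": [...], "test": [...]}

    def __post_init__(self):
        n, l, m = self.sizes
        if self.w_hidden.shape != (l, n) or self.b_hidden.shape != (l,):
            raise ValueError("hidden layer shape inconsistent with sizes")
        if self.w_out.shape != (m, l) or self.b_out.shape != (m,):
            raise ValueError("output layer shape inconsistent with sizes")
        for a in (self.w_hidden, self.b_hidden, self.w_out, self.b_out):
            if not np.isfinite(a).all():
                raise ValueError("weights must be finite")

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sizes": list(self.sizes),
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "scaler": self.scaler.to_dict() if self.scaler else None,
            "train_mse": self.train_mse,
            "val_mse": self.val_mse,
            "test_mse": self.test_mse,
            "pg_reached": self.pg_reached,
            "stop_reason": self.stop_reason,
            "config": self.config.to_dict() if self.config else None,
            "split_indices": self.split_indices,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        return cls(
            sizes=tuple(d["sizes"]),
            w_hidden=np.asarray(d["w_hidden"], dtype=float),
            b_hidden=np.asarray(d["b_hidden"], dtype=float),
            w_out=np.asarray(d["w_out"], dtype=float),
            b_out=np.asarray(d["b_out"], dtype=float),
            scaler=FeatureScaler.from_dict(d["scaler"]) if d.get("scaler") else None,
            train_mse=list(d.get("train_mse", [])),
            val_mse=list(d.get("val_mse", [])),
            test_mse=d.get("test_mse"),
            pg_reached=bool(d.get("pg_reached", False)),
            stop_reason=d.get("stop_reason", "unknown"),
            config=TrainingConfig.from_dict(d["config"]) if d.get("config") else None,
            split_indices=d.get("split_indices"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "NetworkModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def forward(model: NetworkModel, x: np.ndarray, *, scaled: bool = False) -> np.ndarray:
    """Forward pass: ``W_out · s(W_hid · x + b_hid) + b_out``.

    ``x`` is one input vector or an (n, N) column matrix.  The model's
    feature scaler is applied first unless *scaled* is set (raw inputs in
    miniature tests carry no scaler).
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    X = x[:, None] if one_d else x
    if X.shape[0] != model.sizes[0]:
        raise ValueError(f"input length {X.shape[0]} != {model.sizes[0]}")
    if model.scaler is not None and not scaled:
        X = model.scaler.transform(X)
    H = logsig(model.w_hidden @ X + model.b_hidden[:, None])
    Y = model.w_out @ H + model.b_out[:, None]
    return Y[:, 0] if one_d else Y


def evaluate_mse(model: NetworkModel, X: np.ndarray, T: np.ndarray, *, scaled: bool = False) -> float:
    """Mean over all outputs and columns of squared output-target error."""
    Y = forward(model, X, scaled=scaled)
    if Y.shape != np.asarray(T).shape:
        raise ValueError("output/target shape mismatch")
    return float(np.mean((Y - np.asarray(T, dtype=float)) ** 2))


def _mse_and_grads(model, X, T):
    H = logsig(model.w_hidden @ X + model.b_hidden[:, None])
    Y = model.w_out @ H + model.b_out[:, None]
    E = Y - T
    m, N = Y.shape
    mse = float(np.mean(E**2))
    dY = 2.0 * E / (m * N)
    g_w_out = dY @ H.T
    g_b_out = dY.sum(axis=1)
    dH = (model.w_out.T @ dY) * H * (1.0 - H)
    g_w_hidden = dH @ X.T
    g_b_hidden = dH.sum(axis=1)
    return mse, (g_w_hidden, g_b_hidden, g_w_out, g_b_out)


def stratified_split(
    labels: np.ndarray, fractions: tuple[float, float, float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation/test indices, stratified per label.

    Per-label counts are rounded from the fractions; the remainder goes to
    the test partition.
    """
    labels = np.asarray(labels)
    tr, va, te = [], [], []
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        idx = rng.permutation(idx)
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        n_tr = min(n_tr, n)
        n_va = min(n_va, n - n_tr)
        tr.append(idx[:n_tr])
        va.append(idx[n_tr : n_tr + n_va])
        te.append(idx[n_tr + n_va :])
    return (np.sort(np.concatenate(tr)), np.sort(np.concatenate(va)), np.sort(np.concatenate(te)))


def _train_once(X, Y, labels, config, sizes, scale, rng_seed) -> NetworkModel:
    """One training attempt: split, init, adaptive-rate descent, stopping."""
    n = X.shape[0]
    m = Y.shape[0]
    rng = np.random.default_rng(rng_seed)
    i_tr, i_va, i_te = stratified_split(labels, config.split, rng)

    scaler = None
    if scale:
        scaler = FeatureScaler().fit(X[:, i_tr])
        Xs = scaler.transform(X)
    else:
        Xs = X

    l = sizes[1]
    model = NetworkModel(
        sizes=sizes,
        w_hidden=rng.uniform(-0.5, 0.5, size=(l, n)),
        b_hidden=rng.uniform(-0.5, 0.5, size=l),
        w_out=rng.uniform(-0.5, 0.5, size=(m, l)),
        b_out=rng.uniform(-0.5, 0.5, size=m),
        scaler=scaler,
        config=config,
    )

    X_tr, Y_tr = Xs[:, i_tr], Y[:, i_tr]
    X_va, Y_va = Xs[:, i_va], Y[:, i_va]
    X_te, Y_te = Xs[:, i_te], Y[:, i_te]

    def params():
        return (model.w_hidden, model.b_hidden, model.w_out, model.b_out)

    lr = config.learning_rate
    vel = [np.zeros_like(p) for p in params()]
    last: tuple | None = None  # (mse, grads, param snapshot) of last accepted epoch
    best_val = np.inf
    best_weights = None
    rising = 0
    stop_reason = "max_epochs"

    for _ in range(config.max_epochs):
        mse, grads = _mse_and_grads(model, X_tr, Y_tr)
        if last is not None and mse > last[0] * config.max_error_increase:
            # reject the previous step: restore, damp the rate, kill momentum
            mse, grads, snapshot = last
            model.w_hidden, model.b_hidden, model.w_out, model.b_out = (
                a.copy() for a in snapshot
            )
            lr *= config.lr_decrease
            for v in vel:
                v[:] = 0.0
        elif last is not None and mse < last[0]:
            lr *= config.lr_increase

        model.train_mse.append(mse)
        val = evaluate_mse(model, X_va, Y_va, scaled=True) if len(i_va) else np.inf
        model.val_mse.append(val)

        if val < best_val:
            best_val = val
            best_weights = tuple(p.copy() for p in params())
            rising = 0
        else:
            rising += 1

        if mse <= config.pg:
            model.pg_reached = True
            stop_reason = "pg_reached"
            break
        if len(i_va) and rising >= config.patience:
            stop_reason = "validation_rise"
            break

        last = (mse, grads, tuple(p.copy() for p in params()))
        for p, v, g in zip(params(), vel, grads):
            v *= config.momentum
            v -= lr * g
            p += v

    # on a validation stop, fall back to the best-validation weights
    if stop_reason == "validation_rise" and best_weights is not None:
        model.w_hidden, model.b_hidden, model.w_out, model.b_out = best_weights

    model.stop_reason = stop_reason
    model.test_mse = evaluate_mse(model, X_te, Y_te, scaled=True) if len(i_te) else None
    model.split_indices = {
        "train": i_tr.tolist(),
        "val": i_va.tolist(),
        "test": i_te.tolist(),
        "labels": labels.tolist(),
    }
    return model


def train(
    M,
    T,
    config: TrainingConfig,
    *,
    sizes: tuple[int, int, int] | None = None,
    scale: bool = True,
) -> NetworkModel:
    """Train a network on motion/target cells (or pre-stacked matrices).

    ``M``/``T`` are either the per-exercise cell lists from
    :func:`~imurehab.features.build_matrices` or plain (n, N)/(m, N)
    matrices.  Full-batch descent with momentum and an adaptive learning
    rate (steps that inflate the error beyond ``max_error_increase`` are
    rejected and the rate damped; improving steps grow it).  If an attempt
    stops without reaching PG, the split is redrawn and training restarts
    from fresh weights, up to ``config.restarts`` extra attempts, keeping
    the attempt with the best validation MSE.  Returns the model with its
    full MSE history, the held-out test MSE computed once after stopping,
    and the seed-reproducible split.  Exhausting all attempts without
    reaching PG flags the model, it does not raise.
    """
    if isinstance(M, (list, tuple)):
        X, labels = stack_cells(M)
        Y, _ = stack_cells(T)
    else:
        X = np.asarray(M, dtype=float)
        Y = np.asarray(T, dtype=float)
        labels = np.argmax(Y, axis=0) + 1
    if X.shape[1] != Y.shape[1]:
        raise ValueError("motion and target column counts differ")
    n = X.shape[0]
    m = Y.shape[0]
    if sizes is None:
        sizes = (n, DEFAULT_SIZES[1], m)
    if sizes[0] != n or sizes[2] != m:
        raise ValueError("sizes inconsistent with data")

    best: NetworkModel | None = None
    for attempt in range(config.restarts + 1):
        model = _train_once(X, Y, labels, config, sizes, scale, [config.seed, attempt])
        if model.pg_reached:
            return model
        final_val = min(model.val_mse) if model.val_mse else np.inf
        best_final = min(best.val_mse) if best is not None and best.val_mse else np.inf
        if best is None or final_val < best_final:
            best = model
    return best
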