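"""Multilayer-perceptron core: neuron model, backprop, GD and LM trainers.

The working network is a feedforward MLP with 144 inputs (one flattened
12x12 window), 70 tangent-sigmoid hidden neurons and a single linear output:

    n = sum_i w_1i * p_i + b,    Y = f(W . P + b).

Training minimises the mean-squared error between the network output and
the desired target.  Three trainers are provided:

* ``gd``   - full-batch gradient descent backpropagation;
* ``gda``  - gradient descent with an adaptive learning rate (rate grows on
  improvement, shrinks and the step is rejected on a significant worsening);
* ``lm``   - Levenberg-Marquardt: per iteration solve
  (J^T J + lambda I) delta = J^T e for the explicit residual Jacobian J,
  accept the step if the MSE drops (lambda /= down) else reject it
  (lambda *= up).  When the sample count is below the parameter count the
  equivalent dual system (J J^T + lambda I) of size n_samples is solved
  instead, which keeps the method tractable for the 10k-parameter 144-70-1
  network on small window sets.

Everything is deterministic given the seeds: weight initialisation is
uniform in +-1/sqrt(fan_in) from a seeded generator, and the 70/15/15
train/validation/test split shuffles with its own seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MLPModel",
    "TrainingConfig",
    "TrainingRecord",
    "tansig",
    "init_mlp",
    "forward",
    "forward_batch",
    "delta_rule_step",
    "backprop_gradients",
    "train_gd",
    "train_lm",
    "train",
    "split_data",
    "mse",
    "hidden_size_sweep",
]


def tansig(x):
    """Hyperbolic-tangent sigmoid, 2/(1+exp(-2x)) - 1 = tanh(x); odd, range (-1, 1)."""
    return np.tanh(x)


_ACTIVATIONS = {
    "tansig": (tansig, lambda a: 1.0 - a ** 2),
    "linear": (lambda x: x, lambda a: np.ones_like(a)),
}


@dataclass
class MLPModel:
    """Feedforward network: per-layer weight matrices and bias vectors.

    ``weights[l]`` has shape (units_out, units_in); all layers use
    ``hidden_activation`` except the last, which uses ``output_activation``
    (linear by default so the output can act as a score or a regressed
    occupancy fraction).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_activation: str = "tansig"
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        self.weights = [np.asarray(w, dtype=np.float64) for w in self.weights]
        self.biases = [np.asarray(b, dtype=np.float64).ravel() for b in self.biases]
        if len(self.weights) != len(self.biases) or not self.weights:
            raise ValueError("need one bias vector per weight matrix")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2 or w.shape[0] != b.size:
                raise ValueError(f"layer {l}: weight shape {w.shape} vs bias size {b.size}")
            if l > 0 and w.shape[1] != self.weights[l - 1].shape[0]:
                raise ValueError(f"layer {l}: input size {w.shape[1]} does not match "
                                 f"previous layer output {self.weights[l - 1].shape[0]}")
        for name in (self.hidden_activation, self.output_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[1],) + tuple(w.shape[0] for w in self.weights)

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def copy(self) -> "MLPModel":
        return MLPModel([w.copy() for w in self.weights], [b.copy() for b in self.biases],
                        self.hidden_activation, self.output_activation)

    def get_params(self) -> np.ndarray:
        return np.concatenate([np.concatenate([w.ravel(), b])
                               for w, b in zip(self.weights, self.biases)])

    def set_params(self, theta: np.ndarray) -> None:
        i = 0
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[l] = theta[i: i + w.size].reshape(w.shape)
            i += w.size
            self.biases[l] = theta[i: i + b.size].copy()
            i += b.size
        if i != theta.size:
            raise ValueError("parameter vector length mismatch")

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "layer_sizes": list(self.layer_sizes),
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "MLPModel":
        doc = json.loads(Path(path).read_text())
        return cls([np.array(w) for w in doc["weights"]],
                   [np.array(b) for b in doc["biases"]],
                   doc["hidden_activation"], doc["output_activation"])


def init_mlp(layer_sizes=(144, 70, 1), seed: int = 0,
             hidden_activation: str = "tansig",
             output_activation: str = "linear") -> MLPModel:
    """Seeded random network, weights/biases uniform in +-1/sqrt(fan_in)."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        lim = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-lim, lim, size=(fan_out, fan_in)))
        biases.append(rng.uniform(-lim, lim, size=fan_out))
    return MLPModel(weights, biases, hidden_activation, output_activation)


def _forward_all(model: MLPModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer for a batch X (n, R); entry 0 is X."""
    acts = [X]
    last = len(model.weights) - 1
    a = X
    for l, (w, b) in enumerate(zip(model.weights, model.biases)):
        name = model.output_activation if l == last else model.hidden_activation
        a = _ACTIVATIONS[name][0](a @ w.T + b)
        acts.append(a)
    return acts


def forward_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Network outputs for a batch of feature rows; (n,) for a 1-unit output."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.layer_sizes[0]:
        raise ValueError(f"expected features of length {model.layer_sizes[0]}, "
                         f"got shape {X.shape}")
    out = _forward_all(model, X)[-1]
    return out[:, 0] if out.shape[1] == 1 else out


def forward(model: MLPModel, features: np.ndarray) -> float:
    """Output for a single feature vector (scalar for a 1-unit output)."""
    features = np.asarray(features, dtype=np.float64).ravel()
    out = forward_batch(model, features[None, :])
    return float(out[0]) if np.ndim(out) <= 1 else out[0]


def mse(predictions, targets) -> float:
    """Mean of squared residuals."""
    p = np.asarray(predictions, dtype=np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    if p.size != t.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} targets")
    return float(np.mean((p - t) ** 2))


def delta_rule_step(w: np.ndarray, p: np.ndarray, y_desired: float, y: float,
                    alpha: float) -> np.ndarray:
    """Single-neuron delta rule: w <- w + alpha * p * (Y_d - Y)."""
    w = np.asarray(w, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if w.shape != p.shape:
        raise ValueError(f"shape mismatch: w {w.shape} vs p {p.shape}")
    return w + alpha * p * (y_desired - y)


def backprop_gradients(model: MLPModel, X: np.ndarray, y: np.ndarray
                       ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact gradient of the batch MSE w.r.t. every weight and bias.

    Returns (weight_grads, bias_grads) matching the model's structure.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    acts = _forward_all(model, X)
    n = X.shape[0]
    last = len(model.weights) - 1
    out = acts[-1]
    resid = out - y[:, None] if out.shape[1] == 1 else out - y
    # delta at the output: dMSE/dnet, MSE averaged over samples (and outputs)
    name = model.output_activation
    delta = (2.0 / resid.size) * resid * _ACTIVATIONS[name][1](out)
    w_grads: list[np.ndarray] = [None] * len(model.weights)
    b_grads: list[np.ndarray] = [None] * len(model.biases)
    for l in range(last, -1, -1):
        w_grads[l] = delta.T @ acts[l]
        b_grads[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ model.weights[l]) * _ACTIVATIONS[model.hidden_activation][1](acts[l])
    return w_grads, b_grads


@dataclass
class TrainingConfig:
    """Trainer settings; defaults follow common Marquardt/backprop practice."""

    algorithm: str = "lm"  # gd | gda | lm
    learning_rate: float = 0.05
    max_epochs: int = 1000
    lm_lambda_init: float = 1e-3
    lm_lambda_up: float = 10.0
    lm_lambda_down: float = 10.0
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    patience: int = 6
    gradient_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.algorithm not in ("gd", "gda", "lm"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.learning_rate <= 0 and self.algorithm != "lm":
            # alpha = 0 is allowed as the degenerate "no learning" case
            if self.learning_rate < 0:
                raise ValueError("learning_rate must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class TrainingRecord:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    test_mse: float | None = None
    epochs: int = 0
    wall_time_s: float = 0.0
    algorithm: str = ""


def _unpack_data(data):
    """data = (X, y) or (X, y, X_val, y_val)."""
    if len(data) == 2:
        X, y = data
        return (np.asarray(X, float), np.asarray(y, float).ravel(), None, None)
    X, y, Xv, yv = data
    Xv = np.asarray(Xv, float) if Xv is not None and len(Xv) else None
    yv = np.asarray(yv, float).ravel() if Xv is not None else None
    return np.asarray(X, float), np.asarray(y, float).ravel(), Xv, yv


def train_gd(model: MLPModel, data, config: TrainingConfig
             ) -> tuple[MLPModel, TrainingRecord]:
    """Full-batch gradient descent; ``gda`` adds the adaptive learning rate.

    Stops at ``max_epochs``, on validation early-stopping (``patience``
    epochs without a new validation minimum), or aborts on divergence.
    """
    X, y, Xv, yv = _unpack_data(data)
    model = model.copy()
    adaptive = config.algorithm == "gda"
    alpha = config.learning_rate
    rec = TrainingRecord(algorithm=config.algorithm)
    t0 = time.perf_counter()
    best_val, best_epoch = np.inf, 0
    current = mse(forward_batch(model, X), y)
    for epoch in range(1, config.max_epochs + 1):
        w_grads, b_grads = backprop_gradients(model, X, y)
        saved = (model.get_params(), current)
        for l in range(len(model.weights)):
            model.weights[l] = model.weights[l] - alpha * w_grads[l]
            model.biases[l] = model.biases[l] - alpha * b_grads[l]
        current = mse(forward_batch(model, X), y)
        if not np.isfinite(current):
            raise RuntimeError(f"gradient descent diverged at epoch {epoch} (MSE not finite)")
        if adaptive:
            if current > saved[1] * 1.04:  # reject the step, shrink the rate
                model.set_params(saved[0])
                current = saved[1]
                alpha *= 0.7
            else:
                alpha *= 1.05
        rec.train_mse.append(current)
        rec.epochs = epoch
        if Xv is not None:
            v = mse(forward_batch(model, Xv), yv)
            rec.val_mse.append(v)
            if v < best_val - 1e-15:
                best_val, best_epoch = v, epoch
            elif epoch - best_epoch >= config.patience:
                break
    rec.wall_time_s = time.perf_counter() - t0
    return model, rec


def _lm_jacobian(model: MLPModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample Jacobian d out_i / d theta, shape (n, n_params), plus outputs."""
    acts = _forward_all(model, X)
    n = X.shape[0]
    last = len(model.weights) - 1
    out = acts[-1]
    if out.shape[1] != 1:
        raise ValueError("LM trainer supports a single output unit")
    # reverse sweep seeded with d out/d out = 1 per sample
    delta = _ACTIVATIONS[model.output_activation][1](out)  # (n, 1)
    pieces_w: list[np.ndarray] = [None] * len(model.weights)
    pieces_b: list[np.ndarray] = [None] * len(model.biases)
    for l in range(last, -1, -1):
        # d out / d W_l[i, j] = delta[:, i] * acts[l][:, j]
        pieces_w[l] = np.einsum("ni,nj->nij", delta, acts[l]).reshape(n, -1)
        pieces_b[l] = delta
        if l > 0:
            delta = (delta @ model.weights[l]) * _ACTIVATIONS[model.hidden_activation][1](acts[l])
    J = np.concatenate([np.concatenate([pw, pb], axis=1)
                        for pw, pb in zip(pieces_w, pieces_b)], axis=1)
    return J, out[:, 0]


def train_lm(model: MLPModel, data, config: TrainingConfig
             ) -> tuple[MLPModel, TrainingRecord]:
    """Levenberg-Marquardt on the residuals e = Y_d - Y.

    Each outer iteration computes the Jacobian once, then adjusts lambda
    until a step lowers the MSE (accepted-step MSE is strictly decreasing).
    Stops at ``max_epochs`` iterations, when the gradient norm falls below
    ``gradient_tol``, on lambda overflow, or on validation early stopping.
    """
    X, y, Xv, yv = _unpack_data(data)
    model = model.copy()
    lam = config.lm_lambda_init
    rec = TrainingRecord(algorithm="lm")
    t0 = time.perf_counter()
    n_params = model.n_params
    best_val, best_epoch = np.inf, 0
    current = mse(forward_batch(model, X), y)
    for epoch in range(1, config.max_epochs + 1):
        J, out = _lm_jacobian(model, X)
        e = y - out
        g = J.T @ e
        if np.max(np.abs(g)) < config.gradient_tol:
            break
        theta = model.get_params()
        n = X.shape[0]
        dual = n < n_params
        JJt = J @ J.T if dual else J.T @ J
        accepted = False
        while lam < 1e12:
            A = JJt + lam * np.eye(JJt.shape[0])
            try:
                if dual:
                    delta = J.T @ np.linalg.solve(A, e)
                else:
                    delta = np.linalg.solve(A, g)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(f"LM normal matrix singular at lambda={lam:g}") from exc
            model.set_params(theta + delta)
            trial = mse(forward_batch(model, X), y)
            if np.isfinite(trial) and trial < current:
                current = trial
                lam = max(lam / config.lm_lambda_down, 1e-20)
                accepted = True
                break
            lam *= config.lm_lambda_up
        if not accepted:
            model.set_params(theta)
            break
        rec.train_mse.append(current)
        rec.epochs = epoch
        if Xv is not None:
            v = mse(forward_batch(model, Xv), yv)
            rec.val_mse.append(v)
            if v < best_val - 1e-15:
                best_val, best_epoch = v, epoch
            elif epoch - best_epoch >= config.patience:
                break
    rec.wall_time_s = time.perf_counter() - t0
    return model, rec


def train(model: MLPModel, data, config: TrainingConfig
          ) -> tuple[MLPModel, TrainingRecord]:
    """Dispatch to the configured trainer (gd/gda/lm)."""
    if config.algorithm == "lm":
        return train_lm(model, data, config)
    return train_gd(model, data, config)


def split_data(samples, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Seeded disjoint/exhaustive train/validation/test split.

    ``samples`` is any sequence (typically slice indices, so that all
    windows of one slice land in the same partition and cannot leak between
    training and testing).  Sizes are rounded to the nearest integer with
    the test partition taking the remainder; 66 slices at (0.70, 0.15, 0.15)
    split 46/10/10.
    """
    samples = list(samples)
    n = len(samples)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    n_test = n - n_train - n_val
    for frac, size, name in zip(fractions, (n_train, n_val, n_test),
                                ("train", "validation", "test")):
        if frac > 0 and size == 0:
            raise ValueError(f"too few samples ({n}) for a non-empty {name} split")
    idx = np.random.default_rng(seed).permutation(n)
    shuffled = [samples[i] for i in idx]
    return (shuffled[:n_train],
            shuffled[n_train: n_train + n_val],
            shuffled[n_train + n_val:])


def hidden_size_sweep(X, y, hidden_sizes, repeats: int = 10,
                      config: TrainingConfig | None = None,
                      seed: int = 0) -> dict[int, float]:
    """Mean final training MSE per hidden-layer size.

    For each candidate size the network is re-initialised and trained
    ``repeats`` times with distinct seeds and the final MSEs are averaged;
    the best size is the one with the smallest mean MSE.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    config = config or TrainingConfig()
    results: dict[int, float] = {}
    for h in hidden_sizes:
        finals = []
        for r in range(repeats):
            model = init_mlp((X.shape[1], int(h), 1), seed=seed + 1000 * r + int(h))
            trained, rec = train(model, (X, y), config)
            finals.append(rec.train_mse[-1] if rec.train_mse
                          else mse(forward_batch(trained, X), y))
        results[int(h)] = float(np.mean(finals))
    return results
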