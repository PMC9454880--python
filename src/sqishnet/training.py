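"""Backpropagation for the Sqish/LogSQNL network: squared-error loss,
layer gradients, classical-momentum mini-batch SGD and grid search.

The loss is L = 1/2 * sum_j (A2_j - y_j)^2 against a one-hot target
(benign = [1,0], malignant = [0,1]); the published layer gradients are
exactly the derivatives of this loss.  Output layer:

    delta2_j = (A2_j - y_j) * logsqnl'(Z2_j)
    dW2[i,j] = delta2_j * A1_i,     db2[j] = delta2_j

Hidden layer, ``chain_rule`` mode (the complete gradient):

    delta1_i = (sum_j delta2_j * W2[i,j]) * sqish'(Z1_i)
    dW1[k,i] = delta1_i * x_k,      db1[i] = delta1_i

``paper_literal`` mode reproduces the published hidden-layer update, which
gates each (hidden, output) term on the JOINT sign pattern of Z1 and Z2 —
non-zero only when both lie in [0, 2] (factor (2 - Z2)(16 + Z1)/64) or
both in [-2, 0) (factor (2 + Z2)(1 + Z1)/4) — and is therefore zero for
mixed-sign pre-activations and for Z1 > 2 even though Sqish's positive
branch is unbounded.  (The published cases also carry a stray A1 factor
that would break their agreement with the chain rule even on the shared
regimes; the branch polynomials here are the coherent reading without it.)
The two modes coincide whenever every (Z1_i, Z2_j) pair falls in one of
those two joint regimes.  Default mode is ``chain_rule``: mixed-sign cases
occur constantly in practice and training would silently stall without
them.

Training is float throughout; fixed-point quantization is applied after
training for deployment (offline learning, on-device inference).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .activations import logsqnl_derivative, sqish_derivative
from .data import Dataset, fit_standardizer, apply_standardizer, stratified_split
from .network import ForwardTrace, NetworkParams, Topology, forward, initialize_params, predict

__all__ = [
    "TrainingConfig",
    "Gradients",
    "MomentumState",
    "GridSpec",
    "TrainingHistory",
    "squared_error_loss",
    "output_layer_gradients",
    "hidden_layer_gradients",
    "batch_gradients",
    "momentum_step",
    "train",
    "grid_search",
]

GRADIENT_MODES = ("chain_rule", "paper_literal")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the momentum-SGD trainer.

    Defaults are the grid-searched operating point of the reference system:
    learning rate 1/3, momentum 0.9, batch size 100, 4300 epochs.
    """

    learning_rate: float = 1.0 / 3.0
    momentum: float = 0.9
    batch_size: int = 100
    epochs: int = 4300
    seed: int = 0
    gradient_mode: str = "chain_rule"

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.gradient_mode not in GRADIENT_MODES:
            raise ValueError(
                f"unknown gradient_mode {self.gradient_mode!r}; "
                f"choose from {GRADIENT_MODES}"
            )


@dataclass
class Gradients:
    dW1: np.ndarray
    db1: np.ndarray
    dW2: np.ndarray
    db2: np.ndarray


@dataclass
class MomentumState:
    """Velocity tensors; zero before the first step."""

    vW1: np.ndarray
    vb1: np.ndarray
    vW2: np.ndarray
    vb2: np.ndarray

    @classmethod
    def zeros_like(cls, params: NetworkParams) -> "MomentumState":
        return cls(np.zeros_like(params.W1), np.zeros_like(params.b1),
                   np.zeros_like(params.W2), np.zeros_like(params.b2))


@dataclass
class TrainingHistory:
    """Per-epoch loss and accuracy curves."""

    epoch: list = field(default_factory=list)
    loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)

    def to_rows(self):
        return list(zip(self.epoch, self.loss, self.train_accuracy))


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    Y = np.zeros((labels.shape[0], n_classes))
    Y[np.arange(labels.shape[0]), labels] = 1.0
    return Y


def squared_error_loss(A2, y) -> float:
    """1/2 * sum (A2 - y)^2 for one sample (or mean over a batch)."""
    A2 = np.asarray(A2, dtype=float)
    y = np.asarray(y, dtype=float)
    if A2.shape != y.shape:
        raise ValueError(f"shape mismatch: {A2.shape} vs {y.shape}")
    per_sample = 0.5 * np.sum((A2 - y) ** 2, axis=-1)
    return float(np.mean(per_sample))


def output_layer_gradients(trace: ForwardTrace, y, params: NetworkParams):
    """(dW2, db2) for one sample.

    delta2 = (A2 - y) * logsqnl'(Z2); zero wherever Z2 saturates outside
    (-2, 2).
    """
    delta2 = (trace.A2 - np.asarray(y, float)) * logsqnl_derivative(trace.Z2)
    dW2 = np.outer(trace.A1, delta2)
    return dW2, delta2.copy()


def hidden_layer_gradients(trace: ForwardTrace, y, params: NetworkParams,
                           x, mode: str = "chain_rule"):
    """(dW1, db1) for one sample in the requested gradient mode."""
    if mode not in GRADIENT_MODES:
        raise ValueError(f"unknown gradient mode {mode!r}")
    x = np.asarray(x, dtype=float)
    err = trace.A2 - np.asarray(y, float)
    if mode == "chain_rule":
        delta2 = err * logsqnl_derivative(trace.Z2)
        delta1 = (params.W2 @ delta2) * sqish_derivative(trace.Z1)
    else:
        # Published joint-condition update: the (i, j) term survives only
        # when Z1_i and Z2_j fall in the same printed regime.
        Z1, Z2 = trace.Z1, trace.Z2
        pos = ((Z1 >= 0) & (Z1 <= 2))[:, None] & ((Z2 >= 0) & (Z2 <= 2))[None, :]
        neg = ((Z1 >= -2) & (Z1 < 0))[:, None] & ((Z2 >= -2) & (Z2 < 0))[None, :]
        pos_term = (err * (2.0 - Z2))[None, :] * ((16.0 + Z1) / 64.0)[:, None]
        neg_term = (err * (2.0 + Z2))[None, :] * ((1.0 + Z1) / 4.0)[:, None]
        terms = params.W2 * np.where(pos, pos_term, np.where(neg, neg_term, 0.0))
        delta1 = terms.sum(axis=1)
    dW1 = np.outer(x, delta1)
    return dW1, delta1.copy()


def batch_gradients(params: NetworkParams, X, Y,
                    mode: str = "chain_rule") -> Gradients:
    """Gradients of the mean loss over a mini-batch (vectorized)."""
    if mode not in GRADIENT_MODES:
        raise ValueError(f"unknown gradient mode {mode!r}")
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    tr = forward(params, X)
    n = X.shape[0]
    err = tr.A2 - Y
    delta2 = err * logsqnl_derivative(tr.Z2)                 # (n, out)
    dW2 = tr.A1.T @ delta2 / n
    db2 = delta2.mean(axis=0)
    if mode == "chain_rule":
        delta1 = (delta2 @ params.W2.T) * sqish_derivative(tr.Z1)
    else:
        Z1, Z2 = tr.Z1, tr.Z2
        pos = ((Z1 >= 0) & (Z1 <= 2))[:, :, None] \
            & ((Z2 >= 0) & (Z2 <= 2))[:, None, :]
        neg = ((Z1 >= -2) & (Z1 < 0))[:, :, None] \
            & ((Z2 >= -2) & (Z2 < 0))[:, None, :]
        pos_term = (err * (2.0 - Z2))[:, None, :] * ((16.0 + Z1) / 64.0)[:, :, None]
        neg_term = (err * (2.0 + Z2))[:, None, :] * ((1.0 + Z1) / 4.0)[:, :, None]
        terms = params.W2[None] * np.where(pos, pos_term,
                                           np.where(neg, neg_term, 0.0))
        delta1 = terms.sum(axis=2)
    dW1 = X.T @ delta1 / n
    db1 = delta1.mean(axis=0)
    return Gradients(dW1=dW1, db1=db1, dW2=dW2, db2=db2)


def momentum_step(params: NetworkParams, grads: Gradients,
                  state: MomentumState, config: TrainingConfig):
    """Classical momentum: v' = mu*v - lr*g; theta' = theta + v'."""
    lr, mu = config.learning_rate, config.momentum
    new_state = MomentumState(
        vW1=mu * state.vW1 - lr * grads.dW1,
        vb1=mu * state.vb1 - lr * grads.db1,
        vW2=mu * state.vW2 - lr * grads.dW2,
        vb2=mu * state.vb2 - lr * grads.db2,
    )
    new_params = NetworkParams(
        W1=params.W1 + new_state.vW1,
        b1=params.b1 + new_state.vb1,
        W2=params.W2 + new_state.vW2,
        b2=params.b2 + new_state.vb2,
    )
    return new_params, new_state


def train(dataset: Dataset, topology: Topology | None = None,
          config: TrainingConfig | None = None,
          init_params: NetworkParams | None = None):
    """Mini-batch momentum SGD over shuffled epochs.

    ``dataset`` must already be standardized.  Gradients are averaged
    within each batch; the shuffle and initialization both derive from
    ``config.seed``, so a run is fully reproducible.  Returns the final
    parameters and the per-epoch history.
    """
    config = config or TrainingConfig()
    if dataset.n_samples == 0:
        raise ValueError("empty dataset")
    topology = topology or Topology(n_inputs=dataset.n_features)
    if topology.n_inputs != dataset.n_features:
        raise ValueError("topology input size does not match dataset")
    params = (init_params.copy() if init_params is not None
              else initialize_params(topology, config.seed))
    state = MomentumState.zeros_like(params)
    Y = one_hot(dataset.labels, topology.n_outputs)
    rng = np.random.default_rng(config.seed + 1)
    history = TrainingHistory()
    n = dataset.n_samples
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            grads = batch_gradients(params, dataset.X[idx], Y[idx],
                                    config.gradient_mode)
            params, state = momentum_step(params, grads, state, config)
        tr = forward(params, dataset.X)
        history.epoch.append(epoch + 1)
        history.loss.append(squared_error_loss(tr.A2, Y))
        history.train_accuracy.append(float(np.mean(predict(tr) == dataset.labels)))
    return params, history


@dataclass
class GridSpec:
    """Cartesian hyperparameter grid with a held-out evaluation protocol."""

    learning_rates: list = field(default_factory=lambda: [1.0 / 3.0])
    momenta: list = field(default_factory=lambda: [0.9])
    batch_sizes: list = field(default_factory=lambda: [100])
    epochs: list = field(default_factory=lambda: [4300])
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rates", "momenta", "batch_sizes", "epochs"):
            if not getattr(self, name):
                raise ValueError(f"grid list {name} must be non-empty")

    def configs(self):
        for lr, mu, bs, ep in itertools.product(
                self.learning_rates, self.momenta,
                self.batch_sizes, self.epochs):
            yield TrainingConfig(learning_rate=lr, momentum=mu,
                                 batch_size=bs, epochs=ep, seed=self.seed)


def grid_search(dataset: Dataset, topology: Topology | None = None,
                grid: GridSpec | None = None):
    """Exhaustive search over the grid's Cartesian product.

    Each candidate is trained on a stratified (1 - validation_fraction)
    slice (standardized with that slice's statistics) and scored on the
    held-out rest; ties break toward the earliest grid order.  Returns
    (best config, best validation accuracy, all scored candidates).
    """
    grid = grid or GridSpec()
    fit_ds, val_ds = stratified_split(dataset, 1.0 - grid.validation_fraction,
                                      grid.seed)
    stats = fit_standardizer(fit_ds.X, fit_ds.feature_names)
    fit_std = Dataset(apply_standardizer(fit_ds.X, stats), fit_ds.labels,
                      fit_ds.feature_names)
    Xval = apply_standardizer(val_ds.X, stats)
    best = None
    results = []
    for cfg in grid.configs():
        params, _ = train(fit_std, topology, cfg)
        acc = float(np.mean(predict(forward(params, Xval)) == val_ds.labels))
        results.append((cfg, acc))
        if best is None or acc > best[1]:
            best = (cfg, acc)
    return best[0], best[1], results
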