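"""Multilayer perceptron with Levenberg-Marquardt training.

The network uses hyperbolic-tangent (tansig) hidden units and a linear
(purelin) output unit, trained by damped Gauss-Newton least squares: at each
epoch the Jacobian J of the residuals is computed by back-propagation and
the step solves

    (J'J + mu I) delta = J'r,

with the damping factor mu decreased after an accepted step and increased
(step retried) after a rejected one — interpolating between Newton and
gradient descent.  Overfitting is controlled by early stopping: training
halts after a configurable number of consecutive validation-error increases
and the weights with the lowest validation error are restored.

``MLPRegression`` wraps the raw network in a model/results interface: it is
built from target and feature data, ``fit`` normalizes on the training rows,
trains, and returns an ``MLPResults`` carrying predictions, per-partition
metrics and a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .dataset import MinMaxNormalizer, SplitDataset, split_70_15_15
from .metrics import MetricsReport, compute_metrics, R_THRESHOLD, R2_THRESHOLD

__all__ = [
    "MLPNetwork", "TrainConfig", "TrainResult", "EarlyStopping",
    "init_weights", "forward", "train_lm", "architecture_search",
    "MLPRegression", "MLPResults", "save_model", "load_model",
]


@dataclass
class MLPNetwork:
    """Weights and biases of a tansig-hidden / linear-output perceptron.

    ``layer_sizes`` is (n_inputs, hidden..., n_outputs); ``weights[l]`` has
    shape (out_l, in_l) and ``biases[l]`` shape (out_l,).
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        sizes = self.layer_sizes
        if any(s < 1 for s in sizes) or len(sizes) < 2:
            raise ValueError(f"invalid layer sizes {sizes}")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l + 1], sizes[l]) or b.shape != (sizes[l + 1],):
                raise ValueError(f"layer {l} shape mismatch")

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [np.concatenate([w.ravel(), b]) for w, b in zip(self.weights, self.biases)]
        )

    def from_vector(self, theta: np.ndarray) -> "MLPNetwork":
        weights, biases, k = [], [], 0
        for l in range(len(self.layer_sizes) - 1):
            out, inp = self.layer_sizes[l + 1], self.layer_sizes[l]
            weights.append(theta[k:k + out * inp].reshape(out, inp).copy())
            k += out * inp
            biases.append(theta[k:k + out].copy())
            k += out
        return MLPNetwork(self.layer_sizes, weights, biases)

    def copy(self) -> "MLPNetwork":
        return MLPNetwork(self.layer_sizes,
                          [w.copy() for w in self.weights],
                          [b.copy() for b in self.biases])


def init_weights(layer_sizes: Sequence[int], seed: int) -> MLPNetwork:
    """Seeded uniform initialization scaled by layer fan-in.

    Weights and biases of layer l are drawn from U(-s, s) with
    s = 1/sqrt(fan_in); deterministic for a given seed.
    """
    sizes = tuple(int(s) for s in layer_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError(f"layer sizes must be positive, got {sizes}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for l in range(len(sizes) - 1):
        s = 1.0 / math.sqrt(sizes[l])
        weights.append(rng.uniform(-s, s, size=(sizes[l + 1], sizes[l])))
        biases.append(rng.uniform(-s, s, size=sizes[l + 1]))
    return MLPNetwork(sizes, weights, biases)


def _forward_cached(net: MLPNetwork, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; hidden layers tanh, output linear."""
    a = [np.asarray(X, dtype=float)]
    n_layers = len(net.weights)
    for l, (w, b) in enumerate(zip(net.weights, net.biases)):
        z = a[-1] @ w.T + b
        a.append(z if l == n_layers - 1 else np.tanh(z))
    return a


def forward(net: MLPNetwork, X) -> np.ndarray:
    """Network output for a batch of rows (n, n_inputs) -> (n, n_outputs)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.layer_sizes[0]:
        raise ValueError(
            f"input width {X.shape[1]} != network input size {net.layer_sizes[0]}"
        )
    return _forward_cached(net, X)[-1]


def _jacobian(net: MLPNetwork, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Output and d(output)/d(params) for a single-output network.

    Returns (yhat (n,), J (n, n_params)) with parameter ordering matching
    ``to_vector`` (per layer: weights row-major, then biases).
    """
    a = _forward_cached(net, X)
    n = X.shape[0]
    n_layers = len(net.weights)
    yhat = a[-1][:, 0]
    # delta[l] = d yhat / d z_{l+1}, start at output (identity transfer)
    delta = np.ones((n, 1))
    blocks: list[np.ndarray | None] = [None] * n_layers
    for l in range(n_layers - 1, -1, -1):
        jw = np.einsum("no,ni->noi", delta, a[l]).reshape(n, -1)
        blocks[l] = np.concatenate([jw, delta], axis=1)
        if l > 0:
            delta = (delta @ net.weights[l]) * (1.0 - a[l] ** 2)
    return yhat, np.concatenate(blocks, axis=1)


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg-Marquardt training settings.

    Defaults mirror the conventional values of the modelling environment the
    study settings are quoted from: 1000 epochs, validation patience 6,
    mu schedule 0.001 x10 /10 capped at 1e10, error goal 0 and no weight
    decay (L2 regularization deliberately not implemented).
    """

    max_epochs: int = 1000
    validation_patience: int = 6
    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    goal_mse: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.validation_patience < 1:
            raise ValueError("max_epochs and validation_patience must be >= 1")
        if min(self.mu_init, self.mu_increase, self.mu_decrease, self.mu_max) <= 0:
            raise ValueError("mu schedule values must be positive")


class EarlyStopping:
    """Track validation error; signal stop after ``patience`` consecutive
    checks without improvement over the best value seen."""

    def __init__(self, patience: int) -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = math.inf
        self.best_epoch = -1
        self.fails = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record one validation check; return True when training should stop."""
        if value < self.best:
            self.best = value
            self.best_epoch = epoch
            self.fails = 0
        else:
            self.fails += 1
        return self.fails >= self.patience


@dataclass
class TrainResult:
    """Outcome of one Levenberg-Marquardt run (best-validation weights)."""

    network: MLPNetwork
    epochs_run: int
    stop_reason: str               # patience | max_epochs | mu_overflow | goal
    train_trace: np.ndarray        # per-epoch training MSE
    val_trace: np.ndarray          # per-epoch validation MSE
    best_epoch: int


def train_lm(
    net: MLPNetwork,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Train by Levenberg-Marquardt with early stopping.

    Expects normalized data.  Per epoch the Gauss-Newton system is formed
    once (G = J'J, g = J'r) and the damped solve is retried with increasing
    mu until the sum of squared errors decreases; if mu exceeds ``mu_max``
    training stops with reason ``mu_overflow``.  Validation MSE is checked
    every epoch; after ``validation_patience`` consecutive non-improvements
    training stops and the best-validation weights are restored.
    """
    x_train = np.asarray(x_train, float)
    y_train = np.asarray(y_train, float).ravel()
    x_val = np.asarray(x_val, float)
    y_val = np.asarray(y_val, float).ravel()
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation partitions must be non-empty")

    theta = net.to_vector()
    work = net.from_vector(theta)
    n = len(y_train)
    mu = config.mu_init
    stopper = EarlyStopping(config.validation_patience)
    train_trace: list[float] = []
    val_trace: list[float] = []
    best_theta = theta.copy()
    stop_reason = "max_epochs"
    eye = np.eye(work.n_params)

    epoch = 0
    while epoch < config.max_epochs:
        yhat, J = _jacobian(work, x_train)
        r = yhat - y_train
        sse = float(r @ r)
        G = J.T @ J
        g = J.T @ r

        accepted = False
        while mu <= config.mu_max:
            try:
                delta = cho_solve(cho_factor(G + mu * eye, lower=True), g)
            except (LinAlgError, np.linalg.LinAlgError):
                mu *= config.mu_increase
                continue
            cand = theta - delta
            cand_net = work.from_vector(cand)
            r_new = forward(cand_net, x_train)[:, 0] - y_train
            sse_new = float(r_new @ r_new)
            if sse_new < sse:
                theta, work, sse = cand, cand_net, sse_new
                mu = max(mu * config.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= config.mu_increase
        if not accepted:
            stop_reason = "mu_overflow"
            break

        epoch += 1
        train_mse = sse / n
        val_mse = float(np.mean((forward(work, x_val)[:, 0] - y_val) ** 2))
        train_trace.append(train_mse)
        val_trace.append(val_mse)
        if val_mse < stopper.best:
            best_theta = theta.copy()
        if stopper.update(val_mse, epoch):
            stop_reason = "patience"
            break
        if train_mse <= config.goal_mse:
            stop_reason = "goal"
            break

    return TrainResult(
        network=net.from_vector(best_theta),
        epochs_run=epoch,
        stop_reason=stop_reason,
        train_trace=np.asarray(train_trace),
        val_trace=np.asarray(val_trace),
        best_epoch=stopper.best_epoch,
    )


#: Incremental structure schedule: widen the single hidden layer, then append
#: a half-width second layer, then widen again.  The exact intermediate steps
#: between the simplest and the selected structure are an interpretation of
#: the summarized flowchart; the search log records every evaluated step.
DEFAULT_SCHEDULE: tuple[tuple[int, ...], ...] = ((5,), (10,), (20,), (20, 10), (40, 20))


def architecture_search(
    x_train, y_train, x_val, y_val,
    schedule: Sequence[Sequence[int]] = DEFAULT_SCHEDULE,
    r_threshold: float = R_THRESHOLD,
    r2_threshold: float = R2_THRESHOLD,
    config: TrainConfig = TrainConfig(),
) -> tuple[tuple[int, ...], list[dict]]:
    """Incremental hidden-structure search.

    Trains each structure in ``schedule`` (growing parameter count) and
    stops at the first whose validation R and R² clear the satisfaction
    thresholds.  If none does, the best-so-far structure (highest validation
    R², ties toward fewer parameters) is returned with ``satisfied`` False
    in its log entry.  Returns (selected hidden sizes, full search log).
    """
    x_train = np.asarray(x_train, float)
    n_in = x_train.shape[1]
    log: list[dict] = []
    for hidden in schedule:
        sizes = (n_in, *hidden, 1)
        net = init_weights(sizes, config.seed)
        result = train_lm(net, x_train, y_train, x_val, y_val, config)
        pred = forward(result.network, x_val)[:, 0]
        rep = compute_metrics(y_val, pred, partition="validation")
        satisfied = (not math.isnan(rep.R)) and rep.R > r_threshold and rep.R2 > r2_threshold
        entry = {
            "hidden": tuple(hidden),
            "n_params": net.n_params,
            "R": rep.R,
            "R2": rep.R2,
            "val_mse": rep.MSE,
            "satisfied": satisfied,
        }
        log.append(entry)
        if satisfied:
            return tuple(hidden), log
    best = max(log, key=lambda e: ((-1 if math.isnan(e["R2"]) else e["R2"]), -e["n_params"]))
    return best["hidden"], log


class MLPRegression:
    """Single-target MLP regression model over a feature table.

    statsmodels-style usage::

        model = MLPRegression(endog, exog, hidden_layers=(20, 10))
        res = model.fit(seed=0)
        print(res.summary())
        yhat = res.predict(new_exog)

    The constructor takes the full (de-normalized) dataset; ``fit`` draws a
    70:15:15 split, fits min/max normalizers on the training rows only,
    trains with Levenberg-Marquardt + early stopping and evaluates on the
    de-normalized scale.
    """

    def __init__(
        self,
        endog,
        exog: pd.DataFrame,
        hidden_layers: Sequence[int] = (20, 10),
        split: SplitDataset | None = None,
    ) -> None:
        self.endog = pd.Series(np.asarray(endog, float).ravel(), name="target")
        self.exog = pd.DataFrame(exog).reset_index(drop=True)
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        self.hidden_layers = tuple(int(h) for h in hidden_layers)
        self.split = split

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, target: str, features: Sequence[str], **kwargs
    ) -> "MLPRegression":
        missing = [c for c in [target, *features] if c not in df.columns]
        if missing:
            raise KeyError(f"columns not in frame: {missing}")
        return cls(df[target], df[list(features)], **kwargs)

    def fit(self, seed: int = 0, config: TrainConfig | None = None) -> "MLPResults":
        config = config or TrainConfig(seed=seed)
        split = self.split or split_70_15_15(len(self.endog), seed)

        x_norm = MinMaxNormalizer().fit(self.exog.iloc[split.train])
        y_frame = self.endog.to_frame()
        y_norm = MinMaxNormalizer().fit(y_frame.iloc[split.train])
        X = x_norm.transform(self.exog).to_numpy()
        y = y_norm.transform(y_frame).to_numpy().ravel()

        sizes = (X.shape[1], *self.hidden_layers, 1)
        net = init_weights(sizes, seed)
        result = train_lm(
            net, X[split.train], y[split.train], X[split.validation], y[split.validation], config
        )
        return MLPResults(self, result, split, x_norm, y_norm)


class MLPResults:
    """Fitted MLP regression: predictions, per-partition metrics, summary."""

    def __init__(
        self,
        model: MLPRegression,
        train_result: TrainResult,
        split: SplitDataset,
        x_norm: MinMaxNormalizer,
        y_norm: MinMaxNormalizer,
    ) -> None:
        self.model = model
        self.train_result = train_result
        self.split = split
        self.x_norm = x_norm
        self.y_norm = y_norm

    @property
    def network(self) -> MLPNetwork:
        return self.train_result.network

    def predict(self, exog: pd.DataFrame | None = None) -> np.ndarray:
        """De-normalized predictions for ``exog`` (default: the model data)."""
        exog = self.model.exog if exog is None else pd.DataFrame(exog)
        Xn = self.x_norm.transform(exog).to_numpy()
        yn = forward(self.network, Xn)
        out = self.y_norm.inverse_transform(
            pd.DataFrame(yn, columns=self.y_norm.data_min_.index)
        )
        return out.to_numpy().ravel()

    def _partition_idx(self, partition: str) -> np.ndarray:
        if partition == "all":
            return np.arange(len(self.model.endog))
        try:
            return getattr(self.split, partition)
        except AttributeError:
            raise ValueError(f"unknown partition {partition!r}") from None

    def metrics(self, partition: str = "test") -> MetricsReport:
        idx = self._partition_idx(partition)
        pred = self.predict(self.model.exog.iloc[idx])
        return compute_metrics(self.model.endog.iloc[idx], pred, partition=partition)

    def summary(self) -> str:
        tr = self.train_result
        sizes = "-".join(str(s) for s in self.model.hidden_layers)
        lines = [
            "MLP regression results",
            "=" * 62,
            f"structure: {sizes}   inputs: {self.model.exog.shape[1]}"
            f"   parameters: {self.network.n_params}",
            f"epochs: {tr.epochs_run} (best {tr.best_epoch})   stop: {tr.stop_reason}",
            f"{'partition':<12}{'n':>5}{'R':>8}{'R2':>8}{'MSE':>11}{'RMSE':>9}"
            f"{'MAE':>9}{'SD':>9}",
            "-" * 62,
        ]
        for part in ("train", "validation", "test"):
            m = self.metrics(part)
            lines.append(
                f"{part:<12}{m.n:>5}{m.R:>8.3f}{m.R2:>8.3f}{m.MSE:>11.4g}"
                f"{m.RMSE:>9.4g}{m.MAE:>9.4g}{m.SD:>9.4g}"
            )
        return "\n".join(lines)


def save_model(path: str | Path, results: MLPResults) -> None:
    """Serialize a fitted model (sizes, weights, normalization) as JSON."""
    net = results.network
    payload = {
        "layer_sizes": list(net.layer_sizes),
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "x_min": results.x_norm.data_min_.to_dict(),
        "x_max": results.x_norm.data_max_.to_dict(),
        "y_min": results.y_norm.data_min_.to_dict(),
        "y_max": results.y_norm.data_max_.to_dict(),
        "feature_range": list(results.x_norm.feature_range),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[MLPNetwork, MinMaxNormalizer, MinMaxNormalizer]:
    """Inverse of :func:`save_model`; exact round trip of all floats."""
    payload = json.loads(Path(path).read_text())
    net = MLPNetwork(
        tuple(payload["layer_sizes"]),
        [np.asarray(w) for w in payload["weights"]],
        [np.asarray(b) for b in payload["biases"]],
    )
    fr = tuple(payload["feature_range"])
    x_norm = MinMaxNormalizer(fr)
    x_norm.data_min_ = pd.Series(payload["x_min"])
    x_norm.data_max_ = pd.Series(payload["x_max"])
    y_norm = MinMaxNormalizer(fr)
    y_norm.data_min_ = pd.Series(payload["y_min"])
    y_norm.data_max_ = pd.Series(payload["y_max"])
    return net, x_norm, y_norm
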