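"""Multi-task training loop and chemometric evaluation metrics.

Metrics follow the chemometric convention: RC²/RMSEC on the calibration
(training) set, RP²/RMSEP on the prediction (test) set, and
RPD = SD(y_test) / RMSEP with the n-1 standard deviation. An RPD above 2
conventionally indicates a usable calibration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ConfigurationError, SoilSpecError, ValidationError
from .io import SplitPlan
from .models import NetworkHandle
from .nn import Adam, SGD

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "r_squared",
    "rmse",
    "rpd",
    "train",
    "evaluate",
    "UNDEFINED",
]

#: Sentinel reported when a metric is undefined (e.g. R² of a zero-variance target).
UNDEFINED = float("nan")


@dataclass(frozen=True)
class TrainConfig:
    """Training settings.

    Defaults: equal-weight summed MSE over per-attribute standardized
    targets, Adam at 1e-3, batch size 32; early stopping on validation loss
    (patience 20) when the split has a validation partition, otherwise a
    fixed 200 epochs.
    """

    loss: str = "sum_mse"
    task_weights: tuple[float, ...] | None = None
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    early_stopping_patience: int | None = 20
    seed: int = 0
    target_scaling: str = "standardize"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.task_weights is not None and any(w <= 0 for w in self.task_weights):
            raise ConfigurationError("task weights must be positive")
        if self.loss != "sum_mse":
            raise ConfigurationError(f"unsupported loss {self.loss!r}")
        if self.target_scaling not in ("standardize", "none"):
            raise ConfigurationError(f"unknown target_scaling {self.target_scaling!r}")


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Returns the NaN sentinel when the observed values have zero variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValidationError("y and yhat must have the same length")
    if y.size < 2:
        raise ValidationError("R^2 needs at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return UNDEFINED
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValidationError("y and yhat must have the same length")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rpd(y_test: np.ndarray, rmsep: float) -> float:
    """Ratio of performance to deviation: SD(y_test, ddof=1) / RMSEP."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    if y_test.size < 2:
        raise ValidationError("RPD needs at least 2 observations")
    if rmsep == 0:
        warnings.warn("RMSEP is zero; RPD is infinite", stacklevel=2)
        return float("inf")
    return float(np.std(y_test, ddof=1) / rmsep)


@dataclass
class MetricsReport:
    """Per-attribute calibration and prediction metrics."""

    attributes: list[str]
    rc2: dict[str, float] = field(default_factory=dict)
    rmsec: dict[str, float] = field(default_factory=dict)
    rp2: dict[str, float] = field(default_factory=dict)
    rmsep: dict[str, float] = field(default_factory=dict)
    rpd: dict[str, float] = field(default_factory=dict)
    n_per_split: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    def to_text(self) -> str:
        """Plain-text table: one attribute block per row group."""
        lines = [f"{'Attribute':<12}{'RC2':>8}{'RMSEC':>10}{'RP2':>8}{'RMSEP':>10}{'RPD':>8}"]
        for a in self.attributes:
            lines.append(
                f"{a:<12}{self.rc2[a]:>8.3f}{self.rmsec[a]:>10.4f}"
                f"{self.rp2[a]:>8.3f}{self.rmsep[a]:>10.4f}{self.rpd[a]:>8.3f}"
            )
        lines.append("n per split: " + ", ".join(f"{k}={v}" for k, v in self.n_per_split.items()))
        return "\n".join(lines)


def _gather_inputs(x1d, x2d, idx, mode):
    if mode == "single_input":
        return (x1d[idx],)
    if x2d is None:
        raise ValidationError("dual_input model needs spectrogram images")
    return (x1d[idx], x2d[idx])


def _batch_loss_and_grad(net, inputs, y_std, weights):
    """Weighted summed per-task MSE and its gradient wrt predictions."""
    pred = net.forward(inputs, training=True)
    resid = (pred - y_std).astype(np.float64)
    per_task = np.mean(resid**2, axis=0)
    loss = float(np.sum(weights * per_task))
    dpred = (2.0 / y_std.shape[0]) * weights * resid
    return loss, pred, dpred.astype(pred.dtype)


def train(
    handle: NetworkHandle,
    x1d: np.ndarray,
    y: np.ndarray,
    split: SplitPlan,
    cfg: TrainConfig | None = None,
    x2d: np.ndarray | None = None,
) -> dict:
    """Train a network in place by seeded mini-batch gradient descent.

    Targets are standardized per attribute on *training* statistics (the
    scaler is stored on the handle and inverted inside ``predict``), so the
    multi-task loss is scale-balanced across attributes with different
    units. Returns a history dict with per-epoch train (and val) loss.

    Raises on NaN loss and on empty training splits.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != handle.config.n_tasks:
        raise ValidationError(f"targets must be (n, {handle.config.n_tasks})")
    if not np.all(np.isfinite(y)):
        raise ValidationError("targets contain non-finite values")
    train_idx = split.indices.get("train")
    if train_idx is None or train_idx.size == 0:
        raise ValidationError("split has no training samples")
    val_idx = split.indices.get("val")
    if val_idx is not None and val_idx.size == 0:
        val_idx = None

    # target scaling fitted on train only
    if cfg.target_scaling == "standardize":
        mean = y[train_idx].mean(axis=0)
        scale = y[train_idx].std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)  # zero-variance target: leave unscaled
    else:
        mean = np.zeros(y.shape[1])
        scale = np.ones(y.shape[1])
    handle.target_scaler = {"mean": mean.tolist(), "scale": scale.tolist()}
    y_std = (y - mean) / scale

    weights = np.asarray(cfg.task_weights if cfg.task_weights is not None else np.ones(y.shape[1]), dtype=float)
    if weights.shape != (y.shape[1],):
        raise ConfigurationError("task_weights length must equal n_tasks")

    params = handle.net.parameters()
    if cfg.optimizer == "adam":
        opt = Adam(params, lr=cfg.learning_rate)
    elif cfg.optimizer == "sgd":
        opt = SGD(params, lr=cfg.learning_rate)
    else:
        raise ConfigurationError(f"unknown optimizer {cfg.optimizer!r}")

    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "val_loss": []}
    use_early = cfg.early_stopping_patience is not None and val_idx is not None
    best_val, best_state, patience_left = np.inf, None, cfg.early_stopping_patience or 0

    def eval_loss(idx):
        inputs = _gather_inputs(x1d, x2d, idx, handle.mode)
        pred = handle.net.forward(inputs, training=False)
        resid = (pred - y_std[idx]).astype(np.float64)
        return float(np.sum(weights * np.mean(resid**2, axis=0)))

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx.size)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, train_idx.size, cfg.batch_size):
            idx = train_idx[order[start : start + cfg.batch_size]]
            inputs = _gather_inputs(x1d, x2d, idx, handle.mode)
            opt.zero_grad()
            loss, _, dpred = _batch_loss_and_grad(handle.net, inputs, y_std[idx], weights)
            if not np.isfinite(loss):
                raise SoilSpecError(f"NaN/Inf loss at epoch {epoch}; try a lower learning rate")
            handle.net.backward(dpred)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history["train_loss"].append(epoch_loss / n_batches)
        if val_idx is not None:
            vloss = eval_loss(val_idx)
            history["val_loss"].append(vloss)
            if use_early:
                if vloss < best_val - 1e-12:
                    best_val = vloss
                    best_state = [p.value.copy() for p in params]
                    patience_left = cfg.early_stopping_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
    if use_early and best_state is not None:
        for p, v in zip(params, best_state):
            p.value = v
    if not history["val_loss"]:
        del history["val_loss"]
    return history


def evaluate(
    handle: NetworkHandle,
    x1d: np.ndarray,
    y: np.ndarray,
    split: SplitPlan,
    attribute_names: list[str] | None = None,
    x2d: np.ndarray | None = None,
) -> MetricsReport:
    """Compute RC²/RMSEC on train and RP²/RMSEP/RPD on test predictions."""
    y = np.asarray(y, dtype=float)
    names = attribute_names or [f"attr{i}" for i in range(y.shape[1])]
    report = MetricsReport(attributes=list(names))
    train_idx = split.indices["train"]
    test_idx = split.indices["test"]
    pred_train = handle.predict(x1d[train_idx], None if x2d is None else x2d[train_idx])
    pred_test = handle.predict(x1d[test_idx], None if x2d is None else x2d[test_idx])
    for t, name in enumerate(names):
        report.rc2[name] = r_squared(y[train_idx, t], pred_train[:, t])
        report.rmsec[name] = rmse(y[train_idx, t], pred_train[:, t])
        report.rp2[name] = r_squared(y[test_idx, t], pred_test[:, t])
        report.rmsep[name] = rmse(y[test_idx, t], pred_test[:, t])
        report.rpd[name] = rpd(y[test_idx, t], report.rmsep[name])
    report.n_per_split = split.sizes()
    return report
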