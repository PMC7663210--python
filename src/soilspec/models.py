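"""The multi-task spectral networks.

Two architectures are provided:

* ``Multi_CNN_1D`` — a single-input 1-D convolutional network for the
  preprocessed spectral sequence, with a TCN-style residual block of
  dilated convolutions (rates 2 and 4), shared fully-connected trunk and
  one regression head per soil attribute.
* ``Multi_CNN`` (dual) — the same 1-D branch fused (by feature
  concatenation) with a three-layer 2-D convolutional branch over the
  spectrogram image, feeding the shared trunk and per-attribute heads.

``select_mode`` implements the adaptive input selection: small datasets or
short wavelength ranges fall back to the single-input network, large ones
use the dual-stream model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ConfigurationError
from .nn import (
    BatchNorm1D,
    Conv1D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    MaxPool2D,
    ResidualBlock1D,
    Sequential,
)
from .nn.layers import DEFAULT_DTYPE

__all__ = [
    "ModelConfig",
    "ModePolicy",
    "NetworkHandle",
    "build_multicnn_1d",
    "build_multicnn_dual",
    "select_mode",
    "layer_inventory",
    "MIN_INPUT_LENGTH",
]

MIN_INPUT_LENGTH = 32


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults reproduce the stock layout)."""

    input_length: int = 750
    image_size: int = 64
    n_tasks: int = 3
    conv1d_filters: tuple[int, ...] = (64, 128, 64, 64, 64)
    conv1d_kernel: int = 3
    pool1d: int = 5
    dilation_rates: tuple[int, ...] = (2, 4)
    conv2d_specs: tuple[tuple[int, int], ...] = ((5, 64), (3, 128), (3, 256))
    pool2d: int = 2
    fc_sizes: tuple[int, ...] = (128, 64, 1)
    dropout_rate: float = 0.1
    use_weight_norm: bool = True
    use_batch_norm: bool = True

    def __post_init__(self):
        if self.n_tasks < 1:
            raise ConfigurationError("n_tasks must be >= 1")
        if any(f <= 0 for f in self.conv1d_filters) or any(f <= 0 for _, f in self.conv2d_specs):
            raise ConfigurationError("all filter counts must be positive")
        rates = self.dilation_rates
        if any(r & (r - 1) or r < 2 for r in rates) or list(rates) != sorted(set(rates)):
            raise ConfigurationError("dilation rates must be strictly increasing powers of 2")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, obj: dict) -> "ModelConfig":
        obj = dict(obj)
        for key in ("conv1d_filters", "dilation_rates", "fc_sizes"):
            if key in obj:
                obj[key] = tuple(obj[key])
        if "conv2d_specs" in obj:
            obj["conv2d_specs"] = tuple((int(k), int(f)) for k, f in obj["conv2d_specs"])
        return cls(**obj)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _build_1d_body(cfg: ModelConfig, rng, dtype):
    f1, f2, fres, _, f5 = cfg.conv1d_filters
    k = cfg.conv1d_kernel
    layers = [
        Conv1D(1, f1, k, weight_norm=cfg.use_weight_norm, activation="relu", rng=rng, dtype=dtype, name="conv1"),
    ]
    if cfg.use_batch_norm:
        layers.append(BatchNorm1D(f1, dtype=dtype, name="bn1"))
    layers += [
        MaxPool1D(cfg.pool1d),
        Conv1D(f1, f2, k, activation="relu", rng=rng, dtype=dtype, name="conv2"),
        ResidualBlock1D(f2, fres, k, cfg.dilation_rates, cfg.dropout_rate, rng=rng, dtype=dtype),
        Conv1D(fres, f5, k, activation="relu", rng=rng, dtype=dtype, name="conv3"),
        Flatten(),
    ]
    feat = f5 * (cfg.input_length // cfg.pool1d)
    return Sequential(layers), feat


def _build_2d_body(cfg: ModelConfig, rng, dtype):
    layers = []
    c_in, size = 1, cfg.image_size
    for i, (k, f) in enumerate(cfg.conv2d_specs):
        layers.append(Conv2D(c_in, f, k, activation="relu", rng=rng, dtype=dtype, name=f"conv2d_{i + 1}"))
        layers.append(MaxPool2D(cfg.pool2d))
        size //= cfg.pool2d
        c_in = f
    layers.append(Flatten())
    return Sequential(layers), c_in * size * size


class _Heads:
    """Shared FC trunk followed by one linear regression head per task."""

    def __init__(self, in_features, cfg: ModelConfig, rng, dtype):
        fc1, fc2, out = cfg.fc_sizes
        self.trunk = Sequential([
            Dense(in_features, fc1, activation="relu", rng=rng, dtype=dtype, name="fc1"),
            Dense(fc1, fc2, activation="relu", rng=rng, dtype=dtype, name="fc2"),
        ])
        self.heads = [Dense(fc2, out, rng=rng, dtype=dtype, name=f"head{t}") for t in range(cfg.n_tasks)]

    def forward(self, feats, training=False):
        z = self.trunk.forward(feats, training=training)
        return np.concatenate([h.forward(z, training=training) for h in self.heads], axis=1)

    def backward(self, grad):
        dz = sum(h.backward(grad[:, t : t + 1]) for t, h in enumerate(self.heads))
        return self.trunk.backward(dz)

    def parameters(self):
        return self.trunk.parameters() + [p for h in self.heads for p in h.parameters()]


class MultiCNN1DNet:
    """Single-input network: preprocessed spectrum -> n_tasks predictions."""

    mode = "single_input"

    def __init__(self, cfg: ModelConfig, rng, dtype=DEFAULT_DTYPE):
        self.cfg = cfg
        self.body, feat = _build_1d_body(cfg, rng, dtype)
        self.head = _Heads(feat, cfg, rng, dtype)

    def forward(self, inputs, training=False):
        x = inputs[0] if isinstance(inputs, (tuple, list)) else inputs
        if x.ndim == 2:
            x = x[:, :, None]
        return self.head.forward(self.body.forward(x, training=training), training=training)

    def backward(self, grad):
        return self.body.backward(self.head.backward(grad))

    def parameters(self):
        return self.body.parameters() + self.head.parameters()


class MultiCNNDualNet:
    """Dual-stream network: (spectrum, spectrogram image) -> n_tasks predictions."""

    mode = "dual_input"

    def __init__(self, cfg: ModelConfig, rng, dtype=DEFAULT_DTYPE):
        self.cfg = cfg
        self.body1d, feat1 = _build_1d_body(cfg, rng, dtype)
        self.body2d, feat2 = _build_2d_body(cfg, rng, dtype)
        self._split = feat1
        self.head = _Heads(feat1 + feat2, cfg, rng, dtype)

    def forward(self, inputs, training=False):
        x1, x2 = inputs
        if x1.ndim == 2:
            x1 = x1[:, :, None]
        if x2.ndim == 3:
            x2 = x2[:, :, :, None]
        feats = np.concatenate(
            [self.body1d.forward(x1, training=training), self.body2d.forward(x2, training=training)], axis=1
        )
        return self.head.forward(feats, training=training)

    def backward(self, grad):
        dfeat = self.head.backward(grad)
        d1 = self.body1d.backward(dfeat[:, : self._split])
        d2 = self.body2d.backward(dfeat[:, self._split :])
        return d1, d2

    def parameters(self):
        return self.body1d.parameters() + self.body2d.parameters() + self.head.parameters()


@dataclass
class NetworkHandle:
    """A built (possibly trained) network plus its configuration.

    ``predict`` runs the network in evaluation mode (frozen batch-norm
    statistics, no dropout) in mini-batches.
    """

    net: object
    mode: str
    config: ModelConfig
    seed: int
    target_scaler: dict | None = field(default=None)

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.net.parameters()))

    def forward(self, inputs, training=False):
        return self.net.forward(inputs, training=training)

    def predict(self, x1d, x2d=None, batch_size: int = 256) -> np.ndarray:
        """Raw-unit predictions, (n, n_tasks). Inverts target scaling if fitted."""
        n = x1d.shape[0]
        outs = []
        for start in range(0, n, batch_size):
            sl = slice(start, start + batch_size)
            inputs = (x1d[sl],) if self.mode == "single_input" else (x1d[sl], x2d[sl])
            outs.append(self.net.forward(inputs, training=False))
        y = np.concatenate(outs, axis=0).astype(float) if outs else np.empty((0, self.config.n_tasks))
        if self.target_scaler is not None:
            y = y * np.asarray(self.target_scaler["scale"]) + np.asarray(self.target_scaler["mean"])
        return y

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.net.parameters())}
        for i, bn in enumerate(_batchnorms(self.net)):
            arrays[f"bn_{i}_mean"] = bn.running_mean
            arrays[f"bn_{i}_var"] = bn.running_var
        meta = {
            "mode": self.mode,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "target_scaler": self.target_scaler,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "NetworkHandle":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = ModelConfig.from_dict(meta["config"])
            builder = build_multicnn_1d if meta["mode"] == "single_input" else build_multicnn_dual
            handle = builder(cfg, seed=meta["seed"])
            for i, p in enumerate(handle.net.parameters()):
                p.value = data[f"param_{i}"].astype(p.value.dtype)
            for i, bn in enumerate(_batchnorms(handle.net)):
                bn.running_mean = data[f"bn_{i}_mean"]
                bn.running_var = data[f"bn_{i}_var"]
            handle.target_scaler = meta.get("target_scaler")
        return handle


def _bodies(net):
    if isinstance(net, MultiCNN1DNet):
        return [net.body]
    return [net.body1d, net.body2d]


def _batchnorms(net):
    out = []
    for body in _bodies(net):
        out.extend(l for l in body.layers if isinstance(l, BatchNorm1D))
    return out


def _check_input_length(cfg: ModelConfig):
    if cfg.input_length < MIN_INPUT_LENGTH:
        raise ConfigurationError(
            f"input_length {cfg.input_length} too short for pooling and the dilated "
            f"convolution footprint; minimal admissible length is {MIN_INPUT_LENGTH}"
        )


def build_multicnn_1d(cfg: ModelConfig | None = None, seed: int = 0) -> NetworkHandle:
    """Build the single-input Multi_CNN_1D network with seeded initialization."""
    cfg = cfg or ModelConfig()
    _check_input_length(cfg)
    net = MultiCNN1DNet(cfg, np.random.default_rng(seed))
    return NetworkHandle(net, "single_input", cfg, int(seed))


def build_multicnn_dual(cfg: ModelConfig | None = None, seed: int = 0) -> NetworkHandle:
    """Build the dual-stream Multi_CNN network with seeded initialization."""
    cfg = cfg or ModelConfig()
    _check_input_length(cfg)
    if cfg.image_size // cfg.pool2d ** len(cfg.conv2d_specs) < 1:
        raise ConfigurationError("image_size too small for the 2-D pooling stack")
    net = MultiCNNDualNet(cfg, np.random.default_rng(seed))
    return NetworkHandle(net, "dual_input", cfg, int(seed))


@dataclass(frozen=True)
class ModePolicy:
    """Thresholds for adaptive input selection."""

    min_samples: int = 1000
    min_channels: int = 1000


def select_mode(n_samples: int, n_channels: int, policy: ModePolicy | None = None,
                override: str | None = None) -> str:
    """Adaptive input selection.

    Returns ``"single_input"`` for datasets that are small (few samples) or
    have a short wavelength range (few channels), where the dual-stream
    model overfits; otherwise ``"dual_input"``. An explicit ``override``
    ("single_input"/"dual_input") wins unconditionally.
    """
    if override is not None:
        if override not in ("single_input", "dual_input"):
            raise ConfigurationError(f"unknown mode override {override!r}")
        return override
    if n_samples <= 0 or n_channels <= 0:
        raise ConfigurationError("sample and channel counts must be positive")
    policy = policy or ModePolicy()
    if n_samples < policy.min_samples or n_channels < policy.min_channels:
        return "single_input"
    return "dual_input"


def layer_inventory(handle: NetworkHandle) -> list[dict]:
    """Programmatic layer listing (type, kernel, filters, pool, dilation, units).

    Walks the actual layer objects, so the listing reflects what was built,
    not what was configured.
    """
    rows = []

    def walk(layer):
        if isinstance(layer, Sequential):
            for sub in layer.layers:
                walk(sub)
        elif isinstance(layer, Conv1D):
            row = {"layer": "Conv1D", "kernel": layer.kernel, "filters": layer.out_channels}
            if layer.dilation != 1:
                row["dilation"] = layer.dilation
            rows.append(row)
        elif isinstance(layer, Conv2D):
            rows.append({"layer": "Conv2D", "kernel": (layer.kernel, layer.kernel), "filters": layer.out_channels})
        elif isinstance(layer, MaxPool1D):
            rows.append({"layer": "MaxPool1D", "pool": layer.pool})
        elif isinstance(layer, MaxPool2D):
            rows.append({"layer": "MaxPool2D", "pool": (layer.pool, layer.pool)})
        elif isinstance(layer, BatchNorm1D):
            rows.append({"layer": "BatchNorm1D"})
        elif isinstance(layer, ResidualBlock1D):
            walk(layer.main)
            rows.append({"layer": "Conv1D", "kernel": layer.skip.kernel, "filters": layer.skip.out_channels,
                         "role": "residual_skip"})
        elif isinstance(layer, Dense):
            rows.append({"layer": "FC", "units": layer.w.value.shape[1]})

    for body in _bodies(handle.net):
        walk(body)
    walk(handle.net.head.trunk)
    rows.append({"layer": "FC", "units": handle.net.head.heads[0].w.value.shape[1],
                 "heads": len(handle.net.head.heads)})
    return rows
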