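"""Layer implementations. Channels-last throughout; float32 by default.

Convolutions use "same" padding so sequence/image extents are controlled
only by pooling. Dilated 1-D convolutions are non-causal: padding is split
symmetrically around each position.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self):
        self.grad[...] = 0


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []


def _relu(y):
    return np.maximum(y, 0)


class _ConvBase(Layer):
    """Shared weight-norm / activation plumbing for Conv1D and Conv2D.

    The flattened weight matrix W has shape (taps * in_ch, out_ch). With
    weight normalization W = g * V / ||V|| column-wise, where the norm runs
    over each output unit's fan-in; g is initialized to ||V|| so the initial
    effective weights equal V.
    """

    def __init__(self, fan_in, out_channels, rng, weight_norm, activation, dtype, name):
        self.out_channels = out_channels
        self.weight_norm = weight_norm
        self.activation = activation
        self.dtype = dtype
        v = glorot_uniform(rng, fan_in, out_channels, (fan_in, out_channels), dtype)
        if weight_norm:
            self.v = Parameter(v, f"{name}.v")
            self.g = Parameter(np.linalg.norm(v, axis=0).astype(dtype), f"{name}.g")
        else:
            self.w = Parameter(v, f"{name}.w")
        self.b = Parameter(np.zeros(out_channels, dtype=dtype), f"{name}.b")

    def _effective_weight(self) -> np.ndarray:
        if not self.weight_norm:
            return self.w.value
        norm = np.linalg.norm(self.v.value, axis=0)
        self._wn_norm = norm
        self._wn_unit = self.v.value / norm
        return self.g.value * self._wn_unit

    def _weight_grad(self, dW: np.ndarray) -> None:
        if not self.weight_norm:
            self.w.grad += dW
            return
        u = self._wn_unit
        dg = np.sum(dW * u, axis=0)
        self.g.grad += dg
        self.v.grad += (self.g.value / self._wn_norm) * (dW - u * dg)

    def _activate(self, y):
        if self.activation == "relu":
            y = _relu(y)
            self._act_mask = y > 0
        return y

    def _deactivate(self, grad):
        if self.activation == "relu":
            grad = grad * self._act_mask
        return grad

    def parameters(self):
        ps = [self.v, self.g] if self.weight_norm else [self.w]
        return ps + [self.b]


class Conv1D(_ConvBase):
    """1-D convolution, optional dilation and weight normalization, "same" padding."""

    def __init__(self, in_channels, out_channels, kernel=3, dilation=1, weight_norm=False,
                 activation=None, rng=None, dtype=DEFAULT_DTYPE, name="conv1d"):
        self.in_channels = in_channels
        self.kernel = kernel
        self.dilation = dilation
        span = dilation * (kernel - 1)
        self.pad_left = span // 2
        self.pad_right = span - self.pad_left
        super().__init__(kernel * in_channels, out_channels, rng or np.random.default_rng(),
                         weight_norm, activation, dtype, name)

    def _columns(self, xp: np.ndarray, length: int) -> np.ndarray:
        b = xp.shape[0]
        cols = np.empty((b, length, self.kernel, self.in_channels), dtype=self.dtype)
        for j in range(self.kernel):
            off = j * self.dilation
            cols[:, :, j, :] = xp[:, off : off + length, :]
        return cols.reshape(b, length, self.kernel * self.in_channels)

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        b, length, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        self._cols = self._columns(xp, length)
        w = self._effective_weight()
        y = self._cols.reshape(b * length, -1) @ w + self.b.value
        return self._activate(y.reshape(b, length, self.out_channels))

    def backward(self, grad):
        grad = self._deactivate(np.ascontiguousarray(grad, dtype=self.dtype))
        b, length, _ = grad.shape
        g2 = grad.reshape(b * length, self.out_channels)
        cols2 = self._cols.reshape(b * length, -1)
        self._weight_grad(cols2.T @ g2)
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self._effective_weight().T).reshape(b, length, self.kernel, self.in_channels)
        dxp = np.zeros((b, length + self.pad_left + self.pad_right, self.in_channels), dtype=self.dtype)
        for j in range(self.kernel):
            off = j * self.dilation
            dxp[:, off : off + length, :] += dcols[:, :, j, :]
        return dxp[:, self.pad_left : self.pad_left + length, :]


class Conv2D(_ConvBase):
    """2-D convolution with square kernel and "same" padding."""

    def __init__(self, in_channels, out_channels, kernel=3, weight_norm=False,
                 activation=None, rng=None, dtype=DEFAULT_DTYPE, name="conv2d"):
        self.in_channels = in_channels
        self.kernel = kernel
        self.pad_lo = (kernel - 1) // 2
        self.pad_hi = kernel - 1 - self.pad_lo
        super().__init__(kernel * kernel * in_channels, out_channels, rng or np.random.default_rng(),
                         weight_norm, activation, dtype, name)

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        b, h, w_, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_lo, self.pad_hi), (self.pad_lo, self.pad_hi), (0, 0)))
        k = self.kernel
        cols = np.empty((b, h, w_, k * k, self.in_channels), dtype=self.dtype)
        t = 0
        for i in range(k):
            for j in range(k):
                cols[:, :, :, t, :] = xp[:, i : i + h, j : j + w_, :]
                t += 1
        self._cols = cols.reshape(b, h, w_, k * k * self.in_channels)
        wmat = self._effective_weight()
        y = self._cols.reshape(b * h * w_, -1) @ wmat + self.b.value
        return self._activate(y.reshape(b, h, w_, self.out_channels))

    def backward(self, grad):
        grad = self._deactivate(np.ascontiguousarray(grad, dtype=self.dtype))
        b, h, w_, _ = grad.shape
        k = self.kernel
        g2 = grad.reshape(b * h * w_, self.out_channels)
        cols2 = self._cols.reshape(b * h * w_, -1)
        self._weight_grad(cols2.T @ g2)
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self._effective_weight().T).reshape(b, h, w_, k * k, self.in_channels)
        dxp = np.zeros((b, h + k - 1, w_ + k - 1, self.in_channels), dtype=self.dtype)
        t = 0
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w_, :] += dcols[:, :, :, t, :]
                t += 1
        return dxp[:, self.pad_lo : self.pad_lo + h, self.pad_lo : self.pad_lo + w_, :]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length) positions.

    Training uses batch statistics and updates exponential running averages;
    evaluation uses the frozen running statistics.
    """

    def __init__(self, channels, momentum=0.9, eps=1e-5, dtype=DEFAULT_DTYPE, name="bn"):
        self.momentum = momentum
        self.eps = eps
        self.dtype = dtype
        self.gamma = Parameter(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=self.dtype)
        xhat = self._xhat
        self.gamma.grad += np.sum(grad * xhat, axis=(0, 1))
        self.beta.grad += np.sum(grad, axis=(0, 1))
        dxhat = grad * self.gamma.value
        if not self._training:
            return dxhat / self._std
        m = xhat.shape[0] * xhat.shape[1]
        return (dxhat - dxhat.mean(axis=(0, 1)) - xhat * (dxhat * xhat).mean(axis=(0, 1))) / self._std

    def parameters(self):
        return [self.gamma, self.beta]


class MaxPool1D(Layer):
    """Non-overlapping max pooling with stride = pool; trailing remainder dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, training=False):
        b, length, c = x.shape
        lo = length // self.pool
        self._in_length = length
        xr = x[:, : lo * self.pool, :].reshape(b, lo, self.pool, c)
        self._arg = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        b, lo, c = grad.shape
        dxr = np.zeros((b, lo, self.pool, c), dtype=grad.dtype)
        np.put_along_axis(dxr, self._arg[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros((b, self._in_length, c), dtype=grad.dtype)
        dx[:, : lo * self.pool, :] = dxr.reshape(b, lo * self.pool, c)
        return dx


class MaxPool2D(Layer):
    """Non-overlapping square max pooling; trailing remainder dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, training=False):
        p = self.pool
        b, h, w, c = x.shape
        ho, wo = h // p, w // p
        self._in_shape = (b, h, w, c)
        xr = (
            x[:, : ho * p, : wo * p, :]
            .reshape(b, ho, p, wo, p, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, ho, wo, p * p, c)
        )
        self._arg = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad):
        p = self.pool
        b, h, w, c = self._in_shape
        ho, wo = h // p, w // p
        dxr = np.zeros((b, ho, wo, p * p, c), dtype=grad.dtype)
        np.put_along_axis(dxr, self._arg[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        dx = np.zeros((b, h, w, c), dtype=grad.dtype)
        dx[:, : ho * p, : wo * p, :] = (
            dxr.reshape(b, ho, wo, p, p, c).transpose(0, 1, 3, 2, 4, 5).reshape(b, ho * p, wo * p, c)
        )
        return dx


class Dense(Layer):
    def __init__(self, in_features, out_features, activation=None, rng=None, dtype=DEFAULT_DTYPE, name="fc"):
        rng = rng or np.random.default_rng()
        self.activation = activation
        self.dtype = dtype
        self.w = Parameter(glorot_uniform(rng, in_features, out_features, (in_features, out_features), dtype), f"{name}.w")
        self.b = Parameter(np.zeros(out_features, dtype=dtype), f"{name}.b")

    def forward(self, x, training=False):
        self._x = np.ascontiguousarray(x, dtype=self.dtype)
        y = self._x @ self.w.value + self.b.value
        if self.activation == "relu":
            y = _relu(y)
            self._mask = y > 0
        return y

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=self.dtype)
        if self.activation == "relu":
            grad = grad * self._mask
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T

    def parameters(self):
        return [self.w, self.b]


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time. Owns a seeded stream."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(x.dtype) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class ResidualBlock1D(Layer):
    """Dilated-convolution residual block in the TCN style.

    Main path: Conv1D(k=3, dilation=2, weight norm, ReLU) -> Dropout ->
    Conv1D(k=3, dilation=4, weight norm, ReLU) -> Dropout. Skip path: a
    plain Conv1D(k=3) projecting the input to the block width. The two are
    summed and passed through ReLU. Non-causal "same" padding keeps the
    sequence length unchanged.
    """

    def __init__(self, in_channels, channels=64, kernel=3, dilations=(2, 4), dropout=0.1,
                 rng=None, dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng()
        main = []
        c_in = in_channels
        for d in dilations:
            main.append(Conv1D(c_in, channels, kernel, dilation=d, weight_norm=True,
                               activation="relu", rng=rng, dtype=dtype, name=f"res.d{d}"))
            main.append(Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31))))
            c_in = channels
        self.main = Sequential(main)
        self.skip = Conv1D(in_channels, channels, kernel, rng=rng, dtype=dtype, name="res.skip")
        self.dilations = tuple(dilations)
        self.kernel = kernel

    def forward(self, x, training=False):
        y = self.main.forward(x, training=training) + self.skip.forward(x, training=training)
        out = _relu(y)
        self._mask = out > 0
        return out

    def backward(self, grad):
        grad = grad * self._mask
        return self.main.backward(grad) + self.skip.backward(grad)

    def parameters(self):
        return self.main.parameters() + self.skip.parameters()
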