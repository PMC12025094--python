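"""Minimal feed-forward/recurrent layer kit with explicit backprop.

All layers follow the same contract: ``forward(x, train)`` caches whatever
``backward(grad)`` needs, ``backward`` returns the gradient with respect to
the layer input and accumulates parameter gradients in ``self.grads``.
Tensors are batch-first: convolutional/recurrent inputs are ``(B, T, C)``.

The kit covers exactly what the score-regression network needs (1-D
convolution with 'same' padding, batch norm, max pooling with stride 1,
LSTM read out at the final step) rather than aiming for generality.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "BatchNorm1D",
    "ReLU",
    "Sigmoid",
    "MaxPool1D",
    "Dropout",
    "Dense",
    "BiLSTM",
]


class Layer:
    """Base class holding named parameters and their gradients."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def _he_uniform(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Conv1D(Layer):
    """1-D convolution over time, stride 1, 'same' zero padding.

    Input ``(B, T, C_in)`` -> output ``(B, T, C_out)``. Implemented as
    im2col + matmul; the kernel must be odd so 'same' padding is symmetric.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError(f"kernel must be odd, got {kernel}")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.use_bias = bias
        self.params["W"] = _he_uniform(rng, in_ch * kernel, (kernel * in_ch, out_ch))
        if bias:
            self.params["b"] = np.zeros(out_ch)
        self.zero_grad()

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # (B, T, K, C): window k of each output position
        cols = np.stack([xp[:, k:k + T, :] for k in range(self.kernel)], axis=2)
        return cols.reshape(B, T, self.kernel * C)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x)
        y = self._cols @ self.params["W"]
        if self.use_bias:
            y = y + self.params["b"]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, T, C = self._shape
        self.grads["W"] += np.tensordot(self._cols, grad, axes=([0, 1], [0, 1]))
        if self.use_bias:
            self.grads["b"] += grad.sum(axis=(0, 1))
        dcols = (grad @ self.params["W"].T).reshape(B, T, self.kernel, C)
        p = self.kernel // 2
        dxp = np.zeros((B, T + 2 * p, C))
        for k in range(self.kernel):
            dxp[:, k:k + T, :] += dcols[:, :, k, :]
        return dxp[:, p:p + T, :]


class BatchNorm1D(Layer):
    """Batch normalisation per channel over the (batch, time) axes."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(n_ch)
        self.params["beta"] = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = tuple(range(grad.ndim - 1))
        self.grads["gamma"] += (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] += grad.sum(axis=axes)
        dxhat = grad * self.params["gamma"]
        if not self._train:
            return dxhat / self._std
        m = np.prod([grad.shape[a] for a in axes])
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class MaxPool1D(Layer):
    """Max pooling over time, stride 1, 'same' padding: shape-preserving."""

    def __init__(self, kernel: int = 3) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError(f"kernel must be odd, got {kernel}")
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, C = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)), constant_values=-np.inf)
        windows = np.stack([xp[:, k:k + T, :] for k in range(self.kernel)], axis=0)
        self._argmax = windows.argmax(axis=0)
        self._shape = x.shape
        return windows.max(axis=0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, T, C = self._shape
        p = self.kernel // 2
        dxp = np.zeros((B, T + 2 * p, C))
        for k in range(self.kernel):
            dxp[:, k:k + T, :] += grad * (self._argmax == k)
        return dxp[:, p:p + T, :]


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _he_uniform(rng, in_dim, (in_dim, out_dim))
        self.params["b"] = np.zeros(out_dim)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ grad
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"].T


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class _LSTM(Layer):
    """Single-direction LSTM read out at the final hidden state.

    Gate order in the fused weight matrices is (input, forget, cell, output).
    The forget-gate bias starts at 1, the usual remedy for early gradient
    vanishing through the cell state. ``backward`` propagates the gradient of
    the final hidden state only, which is all the regression head consumes.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden
        self.params["Wx"] = _he_uniform(rng, in_dim, (in_dim, 4 * hidden))
        self.params["Wh"] = _he_uniform(rng, hidden, (hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.params["b"] = b
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t, :] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, D = x.shape
        H = self.hidden
        dh = grad
        dc = np.zeros((B, H))
        dx = np.zeros_like(x)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            self.grads["Wx"] += x[:, t, :].T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.params["Wx"].T
            dh = dz @ self.params["Wh"].T
            dc = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: concatenated final hidden states, width 2*hidden."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.fwd = _LSTM(in_dim, hidden, rng)
        self.bwd = _LSTM(in_dim, hidden, rng)
        self.hidden = hidden

    @property
    def sublayers(self) -> list[Layer]:
        return [self.fwd, self.bwd]

    def zero_grad(self) -> None:
        self.fwd.zero_grad()
        self.bwd.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[:, ::-1, :], train)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        H = self.hidden
        dxf = self.fwd.backward(grad[:, :H])
        dxb = self.bwd.backward(grad[:, H:])
        return dxf + dxb[:, ::-1, :]
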