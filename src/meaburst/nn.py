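"""Minimal 1-D convolutional network with backpropagation on numpy.

Sized for the parameter-regression task: inputs are one short channel
(length 500 or 1667), batches of a few hundred windows, and a three-unit
linear output head. Layers implement ``forward``/``backward`` with cached
activations; training uses Adam on a mean-squared-error loss. All
initialization flows from an explicit ``numpy.random.Generator`` so a
seed fixes the weights bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer; stateless layers only implement forward/backward."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding, stride-1 1-D convolution, He-initialized.

    Input ``(n, length, c_in)`` -> output ``(n, length - kernel + 1, c_out)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.w = rng.normal(0.0, scale, size=(kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        # windows: (n, L-k+1, c_in, k)
        win = sliding_window_view(x, self.kernel, axis=1)
        self._win = win
        return np.tensordot(win, self.w, axes=[(3, 2), (0, 1)]) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # dW[k, ci, co] = sum_{n,p} x[n, p+k, ci] * dy[n, p, co]
        self.grads[0][...] = np.tensordot(self._win, dy,
                                          axes=[(0, 1), (0, 1)]).transpose(1, 0, 2)
        self.grads[1][...] = dy.sum(axis=(0, 1))
        # dx via full correlation of dy with flipped kernel
        k = self.kernel
        pad = np.pad(dy, ((0, 0), (k - 1, k - 1), (0, 0)))
        win = sliding_window_view(pad, k, axis=1)  # (n, L, c_out, k)
        wflip = self.w[::-1]                        # (k, c_in, c_out)
        return np.tensordot(win, wflip, axes=[(3, 2), (0, 2)])

    def out_shape(self, in_shape):
        length, _ = in_shape
        return (length - self.kernel + 1, self.w.shape[2])


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def out_shape(self, in_shape):
        return in_shape


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x):
        n, length, c = x.shape
        p = self.pool
        out_len = length // p
        xt = x[:, :out_len * p].reshape(n, out_len, p, c)
        self._argmax = xt.argmax(axis=2)
        self._in_shape = x.shape
        return xt.max(axis=2)

    def backward(self, dy):
        n, out_len, c = dy.shape
        p = self.pool
        dxt = np.zeros((n, out_len, p, c))
        ni, li, ci = np.ogrid[:n, :out_len, :c]
        dxt[ni, li, self._argmax, ci] = dy
        dx = np.zeros(self._in_shape)
        dx[:, :out_len * p] = dxt.reshape(n, out_len * p, c)
        return dx

    def out_shape(self, in_shape):
        length, c = in_shape
        return (length // self.pool, c)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T

    def out_shape(self, in_shape):
        return (self.w.shape[1],)


class Network:
    """A plain layer stack with MSE loss."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(flat, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != {p.shape}")
            p[...] = w

    @property
    def n_params(self) -> int:
        return int(sum(p.size for layer in self.layers for p in layer.params))


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries and its gradient wrt pred."""
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


class Adam:
    def __init__(self, net: Network, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.net = net
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.parameters()]
        self.v = [np.zeros_like(p) for p, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.net.parameters()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
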