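"""Minimal CPU neural-network stack: 3x3 convolutions (im2col), max pooling,
dense layers, Glorot-uniform initialization, and Adam on a mean-squared-error
loss.  Inputs are NHWC float32.  Everything is deterministic given the
initialization seed and a fixed batch order.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Layer):
    """3x3 convolution, stride 1, zero ("same") padding."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = in_channels, out_channels
        fan_in, fan_out = 9 * in_channels, 9 * out_channels
        self.w = glorot_uniform(rng, (9 * in_channels, out_channels), fan_in, fan_out)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        padded = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((n, h, w, 9, c), dtype=x.dtype)
        for i in range(3):
            for j in range(3):
                cols[:, :, :, 3 * i + j, :] = padded[:, i : i + h, j : j + w, :]
        return cols.reshape(n, h, w, 9 * c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = self._im2col(x)
        self._in_shape = x.shape
        return self._cols @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = grad.shape
        flat_cols = self._cols.reshape(-1, 9 * self.cin)
        flat_grad = grad.reshape(-1, self.cout)
        self.grads[0][...] = flat_cols.T @ flat_grad
        self.grads[1][...] = flat_grad.sum(axis=0)
        dcols = (flat_grad @ self.w.T).reshape(n, h, w, 9, self.cin)
        dx_padded = np.zeros((n, h + 2, w + 2, self.cin), dtype=grad.dtype)
        for i in range(3):
            for j in range(3):
                dx_padded[:, i : i + h, j : j + w, :] += dcols[:, :, :, 3 * i + j, :]
        return dx_padded[:, 1 : 1 + h, 1 : 1 + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/columns that do not fill a
    window are cropped.  Gradient is routed to every tied maximum."""

    def __init__(self, pool: tuple[int, int]):
        super().__init__()
        self.ph, self.pw = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = h // self.ph, w // self.pw
        self._in_shape = x.shape
        x = x[:, : ho * self.ph, : wo * self.pw, :]
        blocks = x.reshape(n, ho, self.ph, wo, self.pw, c)
        out = blocks.max(axis=(2, 4))
        self._blocks = blocks
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        ho, wo = grad.shape[1], grad.shape[2]
        mask = self._blocks == self._out[:, :, None, :, None, :]
        dblocks = mask * grad[:, :, None, :, None, :]
        dx = np.zeros((n, h, w, c), dtype=grad.dtype)
        dx[:, : ho * self.ph, : wo * self.pw, :] = dblocks.reshape(
            n, ho * self.ph, wo * self.pw, c)
        return dx

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return h // self.ph, w // self.pw


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            if p.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != expected {p.shape}")
            p[...] = w

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: Adam) -> float:
        """One Adam step on the MSE loss; returns the batch loss."""
        pred = self.forward(x)[:, 0]
        err = pred - y
        loss = float(np.mean(err ** 2))
        self.backward((2.0 * err / len(y))[:, None].astype(np.float32))
        optimizer.step(self.grads)
        return loss
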