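"""Minimal CPU neural-network layers (numpy, float32).

Forward passes cache what the backward pass needs; ``backward`` consumes
the upstream gradient and stores parameter gradients on the layer.
Convolutions are 3x3, stride 1, zero-padded, computed as im2col matmuls.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list  # list of [name, array]

    def __init__(self) -> None:
        self.params = []
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 same-padding convolution, NCHW."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * 9
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.w = w.astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [("w", self.w), ("b", self.b)]
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        # edge-replicate padding: spatially constant input stays constant
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (n, c, h, w, 3, 3)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        y = cols @ self.w + self.b
        if train:
            self._cols = cols
            self._shape = (n, c, h, w)
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c, h, w = self._shape
        dy_ = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.grads = {"w": self._cols.T @ dy_, "b": dy_.sum(axis=0)}
        dcols = (dy_ @ self.w.T).reshape(n, h, w, c, 3, 3).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[..., i, j]
        del self._cols
        # fold the edge-replicated padding gradients back onto the border pixels
        dxp[:, :, 1, :] += dxp[:, :, 0, :]
        dxp[:, :, -2, :] += dxp[:, :, -1, :]
        dxp[:, :, :, 1] += dxp[:, :, :, 0]
        dxp[:, :, :, -2] += dxp[:, :, :, -1]
        return dxp[:, :, 1:-1, 1:-1]


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : h2 * 2, : w2 * 2]
        xr = xc.reshape(n, c, h2, 2, w2, 2)
        if not train:
            return xr.max(axis=(3, 5))
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._idx = idx
        self._shape = (n, c, h, w)
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            dxr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).astype(np.float32)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [("w", self.w), ("b", self.b)]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.grads = {"w": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.w.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-12))))
    g = p
    g[np.arange(n), labels] -= 1.0
    return loss, (g / n).astype(np.float32)


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 2e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{name: np.zeros_like(p) for name, p in ly.params} for ly in self.layers]
        self.v = [{name: np.zeros_like(p) for name, p in ly.params} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, ly in enumerate(self.layers):
            for name, p in ly.params:
                g = ly.grads[name].astype(np.float32)
                m = self.m[i][name]
                v = self.v[i][name]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
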