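"""Feedforward regression MLP with a range-bounded output.

Two rectified-linear hidden layers feed one linear unit whose pre-activation
is squashed through a scaled logistic, confining predictions to [0, s_max]
— the numeric range of the pathologist score being regressed.  Trained by
full-batch Adam on mean squared error.
"""

from __future__ import annotations

import json

import numpy as np
from scipy.special import expit


def bounded_activation(z, s_max: float):
    """Scaled logistic ``s_max * sigma(z)``: strictly increasing, limits 0 and s_max."""
    if s_max <= 0:
        raise ValueError("s_max must be positive")
    return s_max * expit(z)


class BoundedRegressionMLP:
    """MLP: d_in -> hidden[0] -> hidden[1] -> 1, output through ``bounded_activation``."""

    def __init__(self, d_in: int, s_max: float, hidden: tuple[int, int] = (16, 8), seed: int = 0):
        self.d_in = int(d_in)
        self.s_max = float(s_max)
        self.hidden = tuple(int(h) for h in hidden)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        dims = [self.d_in, *self.hidden, 1]
        self.w = [rng.normal(0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1])) for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        # input standardization, fitted before training
        self.x_mean = np.zeros(self.d_in)
        self.x_scale = np.ones(self.d_in)

    def _forward(self, x: np.ndarray):
        h1 = np.maximum(x @ self.w[0] + self.b[0], 0.0)
        h2 = np.maximum(h1 @ self.w[1] + self.b[1], 0.0)
        z = (h2 @ self.w[2] + self.b[2])[:, 0]
        return h1, h2, z

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.d_in:
            raise ValueError(f"expected input dim {self.d_in}, got {x.shape[1]}")
        xs = (x - self.x_mean) / self.x_scale
        return bounded_activation(self._forward(xs)[2], self.s_max)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 2000,
        lr: float = 0.01,
        l2: float = 1e-3,
        seed: int | None = None,
    ) -> list[float]:
        """Minimize MSE with full-batch Adam; returns the per-epoch loss curve.

        A small L2 penalty on the weights keeps the network smooth between
        the few dozen training slides a cohort provides.
        """
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self.x_mean = x.mean(axis=0)
        self.x_scale = np.where(x.std(axis=0) > 1e-12, x.std(axis=0), 1.0)
        xs = (x - self.x_mean) / self.x_scale
        n = len(y)
        m = [np.zeros_like(w) for w in self.w] + [np.zeros_like(b) for b in self.b]
        v = [np.zeros_like(g) for g in m]
        b1, b2, eps = 0.9, 0.999, 1e-8
        curve: list[float] = []
        for t in range(1, epochs + 1):
            h1, h2, z = self._forward(xs)
            sig = expit(z)
            pred = self.s_max * sig
            err = pred - y
            loss = float(np.mean(err**2))
            curve.append(loss)
            dz = (2.0 / n) * err * self.s_max * sig * (1 - sig)
            dw2 = h2.T @ dz[:, None]
            db2 = np.array([dz.sum()])
            dh2 = np.outer(dz, self.w[2][:, 0]) * (h2 > 0)
            dw1 = h1.T @ dh2
            db1 = dh2.sum(axis=0)
            dh1 = (dh2 @ self.w[1].T) * (h1 > 0)
            dw0 = xs.T @ dh1
            db0 = dh1.sum(axis=0)
            if l2:
                dw0 = dw0 + l2 * self.w[0]
                dw1 = dw1 + l2 * self.w[1]
                dw2 = dw2 + l2 * self.w[2]
            grads = [dw0, dw1, dw2, db0, db1, db2]
            params = [*self.w, *self.b]
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g * g
                p -= lr * (m[i] / (1 - b1**t)) / (np.sqrt(v[i] / (1 - b2**t)) + eps)
        return curve

    def save(self, path) -> None:
        meta = {"d_in": self.d_in, "s_max": self.s_max, "hidden": list(self.hidden), "seed": self.seed}
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            x_mean=self.x_mean,
            x_scale=self.x_scale,
            **{f"w{i}": w for i, w in enumerate(self.w)},
            **{f"b{i}": b for i, b in enumerate(self.b)},
        )

    @classmethod
    def load(cls, path) -> "BoundedRegressionMLP":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(meta["d_in"], meta["s_max"], tuple(meta["hidden"]), meta["seed"])
        model.x_mean = data["x_mean"]
        model.x_scale = data["x_scale"]
        model.w = [data[f"w{i}"] for i in range(3)]
        model.b = [data[f"b{i}"] for i in range(3)]
        return model
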