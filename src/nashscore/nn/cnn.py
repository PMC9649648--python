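"""A small convolutional image classifier trained on CPU.

Four conv-relu-pool blocks followed by global average pooling and a
softmax head.  Designed for 299 px histology tiles resized to a modest
square input (default 96 px); deterministic given a seed.
"""

from __future__ import annotations

import json

import numpy as np
from skimage.transform import resize

from .layers import Adam, Conv3x3, Dense, GlobalAvgPool, MaxPool2, ReLU, softmax, softmax_xent

DEFAULT_CHANNELS = (16, 32, 48, 64)


def preprocess_tiles(tiles: np.ndarray, input_px: int) -> np.ndarray:
    """uint8 NHWC tiles -> float32 NCHW, resized and standardized.

    When the tile side is close to an integer multiple of ``input_px`` the
    downscale uses a centered crop plus block averaging (fast, alias-free);
    otherwise an anti-aliased interpolating resize.
    """
    tiles = np.asarray(tiles)
    if tiles.ndim == 3:
        tiles = tiles[None]
    n, h, w = tiles.shape[:3]
    out = np.empty((n, 3, input_px, input_px), dtype=np.float32)
    factor = min(h, w) // input_px
    fast = (
        h == w
        and factor >= 1
        and (h - factor * input_px) <= 0.05 * h
        and (h, w) != (input_px, input_px)
    )
    if fast:
        side = factor * input_px
        off = (h - side) // 2
        cropped = tiles[:, off : off + side, off : off + side].astype(np.float32)
        pooled = cropped.reshape(n, input_px, factor, input_px, factor, 3).mean(axis=(2, 4))
        pooled /= 255.0
        pooled -= 0.5
        pooled /= 0.25
        return np.ascontiguousarray(pooled.transpose(0, 3, 1, 2))
    for i in range(n):
        t = tiles[i]
        if t.shape[0] != input_px or t.shape[1] != input_px:
            t = resize(t, (input_px, input_px), anti_aliasing=True, preserve_range=True)
        out[i] = (t.astype(np.float32) / 255.0 - 0.5).transpose(2, 0, 1) / 0.25
    return out


class SmallCNN:
    """Compact conv net: [conv3x3-relu-maxpool2] x blocks -> GAP -> dense."""

    def __init__(self, n_classes: int, input_px: int = 96, channels: tuple[int, ...] = DEFAULT_CHANNELS, seed: int = 0):
        self.n_classes = int(n_classes)
        self.input_px = int(input_px)
        self.channels = tuple(int(c) for c in channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c_prev = 3
        for c in self.channels:
            self.layers += [Conv3x3(c_prev, c, rng), ReLU(), MaxPool2()]
            c_prev = c
        self.layers += [GlobalAvgPool(), Dense(c_prev, self.n_classes, rng)]
        # index of the activation of the last convolutional stage (post-ReLU)
        self._last_conv_act = len(self.layers) - 4

    # ------------------------------------------------------------------ core
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for ly in self.layers:
            x = ly.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for ly in reversed(self.layers):
            g = ly.backward(g)

    def predict_logits(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        outs = [self.forward(x[i : i + batch]) for i in range(0, x.shape[0], batch)]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        return softmax(self.predict_logits(x, batch=batch).astype(np.float64))

    # ---------------------------------------------------------------- training
    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int = 10,
        batch_size: int = 32,
        lr: float = 2e-3,
        augment: bool = True,
        class_weighted_sampling: bool = True,
        seed: int = 0,
        verbose: bool = False,
    ) -> list[dict]:
        """Train with Adam on softmax cross-entropy; returns per-epoch history."""
        rng = np.random.default_rng(seed)
        opt = Adam(self.layers, lr=lr)
        # step decay stabilizes the class boundaries late in training
        decay_points = {int(epochs * 0.6): 0.3, int(epochs * 0.85): 0.3}
        n = x_train.shape[0]
        if class_weighted_sampling:
            counts = np.bincount(y_train, minlength=self.n_classes).astype(np.float64)
            w = 1.0 / np.maximum(counts[y_train], 1.0)
            w /= w.sum()
        else:
            w = None
        history: list[dict] = []
        steps = max(1, n // batch_size)
        for epoch in range(epochs):
            if epoch in decay_points:
                opt.lr *= decay_points[epoch]
            ep_loss, ep_correct, ep_n = 0.0, 0, 0
            for _ in range(steps):
                idx = rng.choice(n, size=min(batch_size, n), replace=True, p=w)
                xb = x_train[idx]
                yb = y_train[idx]
                if augment:
                    xb = _augment_batch(xb, rng)
                logits = self.forward(xb, train=True)
                loss, dlogits = softmax_xent(logits, yb)
                self.backward(dlogits)
                opt.step()
                ep_loss += loss * len(yb)
                ep_correct += int((logits.argmax(axis=1) == yb).sum())
                ep_n += len(yb)
            rec = {
                "epoch": epoch,
                "train_loss": ep_loss / ep_n,
                "train_accuracy": ep_correct / ep_n,
            }
            if x_val is not None and len(x_val):
                val_logits = self.predict_logits(x_val)
                val_loss, _ = softmax_xent(val_logits, y_val)
                rec["val_loss"] = val_loss
                rec["val_accuracy"] = float((val_logits.argmax(axis=1) == y_val).mean())
            if verbose:
                print(f"epoch {epoch}: {rec}")
            history.append(rec)
        return history

    # ------------------------------------------------------------------- CAM
    def grad_cam(self, x: np.ndarray, target_class: int) -> tuple[np.ndarray, float]:
        """Raw gradient-weighted class activation map for one input.

        Returns the un-normalized (ReLU'd) map at the resolution of the
        last convolutional stage, plus the softmax confidence for
        ``target_class``.  Callers upsample and normalize.
        """
        if x.ndim == 3:
            x = x[None]
        acts = x
        caches = []
        for ly in self.layers:
            acts = ly.forward(acts, train=True)
            caches.append(acts)
        logits = acts
        probs = softmax(logits.astype(np.float64))
        conf = float(probs[0, target_class])
        dlog = np.zeros_like(logits, dtype=np.float32)
        dlog[0, target_class] = 1.0
        g = dlog
        for ly in reversed(self.layers[self._last_conv_act + 1 :]):
            g = ly.backward(g)
        a = caches[self._last_conv_act][0]  # (C, h, w)
        weights = g[0].mean(axis=(1, 2))  # (C,)
        cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
        return cam, conf

    # ---------------------------------------------------------------- weights
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, ly in enumerate(self.layers):
            for name, p in ly.params:
                out[f"layer{i}_{name}"] = p.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, ly in enumerate(self.layers):
            for name, p in ly.params:
                p[...] = weights[f"layer{i}_{name}"]

    def weights_checksum(self) -> float:
        return float(sum(np.abs(p).sum() for ly in self.layers for _, p in ly.params))

    def save(self, path) -> None:
        meta = {
            "n_classes": self.n_classes,
            "input_px": self.input_px,
            "channels": list(self.channels),
            "seed": self.seed,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.get_weights())

    @classmethod
    def load(cls, path) -> "SmallCNN":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(meta["n_classes"], meta["input_px"], tuple(meta["channels"]), meta["seed"])
        model.set_weights({k: data[k] for k in data.files if k != "__meta__"})
        return model


def _augment_batch(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal/vertical flips and 90-degree rotations (NCHW)."""
    xb = xb.copy()
    for i in range(xb.shape[0]):
        if rng.random() < 0.5:
            xb[i] = xb[i, :, :, ::-1]
        if rng.random() < 0.5:
            xb[i] = xb[i, :, ::-1, :]
        k = int(rng.integers(0, 4))
        if k:
            xb[i] = np.rot90(xb[i], k=k, axes=(1, 2))
    return xb
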