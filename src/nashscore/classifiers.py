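"""Tile classification: specs, dataset splitting, training, inference, CAM.

One classifier per histological feature, each with the feature's numeric
class scheme plus an ignore class for artifacts/non-liver structure.
Ballooning, inflammation and steatosis operate on high-resolution tiles
(0.44 µm/px), fibrosis on low-resolution tiles (1.32 µm/px).  The default
backbone is a compact four-block CNN sized for CPU training; warm-start
initialization from a prior checkpoint reproduces the transfer-learning
mechanism (pretraining on a related tile corpus before fine-tuning).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import IGNORE, TILE_PX, FeatureScheme, default_scheme
from .nn.cnn import DEFAULT_CHANNELS, SmallCNN, preprocess_tiles

BACKBONES = ("small_cnn",)


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one feature's tile classifier."""

    feature: str
    scheme: FeatureScheme = None  # type: ignore[assignment]
    backbone: str = "small_cnn"
    pretrained_mode: str = "none"  # none | imagenet | imagenet+domain
    input_px: int = 96
    channels: tuple[int, ...] = DEFAULT_CHANNELS
    tile_px: int = TILE_PX

    def __post_init__(self) -> None:
        if self.scheme is None:
            object.__setattr__(self, "scheme", default_scheme(self.feature))
        if self.scheme.feature != self.feature:
            raise ValueError("scheme feature mismatch")
        if (self.feature == "fibrosis") != (self.scale == "low"):
            raise ValueError("fibrosis uses the low scale; all other features the high scale")
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; available: {BACKBONES}")
        if self.pretrained_mode not in ("none", "imagenet", "imagenet+domain"):
            raise ValueError(f"invalid pretrained_mode {self.pretrained_mode!r}")

    @property
    def scale(self) -> str:
        return "low" if self.feature == "fibrosis" else "high"

    @property
    def n_heads(self) -> int:
        """Output units: numeric classes + the ignore class."""
        return self.scheme.n_classes + 1

    @property
    def ignore_index(self) -> int:
        return self.scheme.n_classes


@dataclass
class TrainingHistory:
    """Per-epoch learning curves plus the final validation confusion matrix."""

    frame: pd.DataFrame
    confusion: np.ndarray  # (n_heads, n_heads) counts, rows = truth
    final_val_accuracy: float

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def split_tiles(labels, train_frac: float = 0.95, seed: int = 0):
    """Stratified random split of labelled tiles into train/validation.

    Returns ``(train_idx, val_idx)`` index arrays: disjoint, exhaustive,
    reproducible by seed.  Classes with fewer than 2 tiles stay whole in
    the train set (with a warning); ``train_frac=1.0`` yields an empty
    validation set with a warning.
    """
    labels = np.asarray(labels)
    if not 0 < train_frac <= 1.0:
        raise ValueError("train_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            warnings.warn(f"class {cls!r} has < 2 tiles; kept whole in train", stacklevel=2)
            train_idx.extend(idx)
            continue
        idx = rng.permutation(idx)
        n_val = int(round((1.0 - train_frac) * len(idx)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    if not val_idx:
        warnings.warn("validation set is empty", stacklevel=2)
    return np.sort(np.asarray(train_idx, dtype=int)), np.sort(np.asarray(val_idx, dtype=int))


class TileClassifier:
    """A trained (or freshly initialized) tile classifier for one feature."""

    def __init__(self, spec: ClassifierSpec, seed: int = 0, model: SmallCNN | None = None):
        self.spec = spec
        self.model = model or SmallCNN(spec.n_heads, spec.input_px, spec.channels, seed=seed)

    # ------------------------------------------------------------ inference
    def classify_tiles(self, tiles: np.ndarray, batch: int = 64) -> np.ndarray:
        """Probability vectors over (numeric classes..., ignore), order-preserving."""
        x = preprocess_tiles(tiles, self.spec.input_px)
        return self.model.predict_proba(x, batch=batch)

    def classify_tile(self, tile: np.ndarray) -> np.ndarray:
        if tile.ndim != 3:
            raise ValueError("expected one RGB tile")
        if tile.shape[0] != self.spec.tile_px or tile.shape[1] != self.spec.tile_px:
            raise ValueError(
                f"expected {self.spec.tile_px} px tile for feature {self.spec.feature!r}, got {tile.shape[:2]}"
            )
        return self.classify_tiles(tile[None])[0]

    def class_activation_map(self, tile: np.ndarray, target_class) -> tuple[np.ndarray, float]:
        """Gradient-weighted CAM for ``target_class``, upsampled to tile size.

        Returns ``(map, confidence)``; the map is min-max normalized to
        [0, 1] (all zeros when spatially constant) and aligned to the tile.
        """
        from skimage.transform import resize

        head = self._head_index(target_class)
        x = preprocess_tiles(tile[None] if tile.ndim == 3 else tile, self.spec.input_px)
        cam, conf = self.model.grad_cam(x[0], head)
        out = resize(cam, tile.shape[:2] if tile.ndim == 3 else tile.shape[1:3], order=1, preserve_range=True)
        spread = float(out.max() - out.min())
        if spread < 1e-8 * max(float(np.abs(out).max()), 1e-12) or spread < 1e-12:
            return np.zeros_like(out), conf  # no spatial signal -> 0 by convention
        return (out - out.min()) / spread, conf

    def _head_index(self, label) -> int:
        if label == IGNORE:
            return self.spec.ignore_index
        values = self.spec.scheme.class_values
        if label not in values:
            raise ValueError(f"unknown class {label!r} for feature {self.spec.feature!r}")
        return values.index(label)

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        path = Path(path)
        self.model.save(path)
        meta = {
            "feature": self.spec.feature,
            "backbone": self.spec.backbone,
            "pretrained_mode": self.spec.pretrained_mode,
            "input_px": self.spec.input_px,
            "channels": list(self.spec.channels),
            "tile_px": self.spec.tile_px,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "TileClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = ClassifierSpec(
            feature=meta["feature"],
            backbone=meta["backbone"],
            pretrained_mode=meta["pretrained_mode"],
            input_px=meta["input_px"],
            channels=tuple(meta["channels"]),
            tile_px=meta["tile_px"],
        )
        return cls(spec, model=SmallCNN.load(path))


def export_cam(tile: np.ndarray, cam: np.ndarray, confidence: float, path) -> Path:
    """Write a CAM overlay PNG (tile blended with a heat colormap) plus the
    raw map as CSV next to it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(tile)
    ax.imshow(cam, cmap="jet", alpha=0.4, vmin=0, vmax=1)
    ax.set_title(f"confidence {confidence:.2f}")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    np.savetxt(path.with_suffix(".csv"), cam, fmt="%.5f", delimiter=",")
    return path


def load_tile_dataset(root) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load a labelled-tile dataset laid out as one directory per class.

    Returns ``(tiles, labels, class_names)`` with labels as indices into the
    sorted class-directory names.  The ``ignore`` directory, when present,
    sorts last so labels line up with classifier head indices.
    """
    import imageio.v3 as iio

    root = Path(root)
    class_dirs = sorted((d for d in root.iterdir() if d.is_dir()), key=lambda d: (d.name == IGNORE, d.name))
    if not class_dirs:
        raise ValueError(f"no class directories under {root}")
    tiles, labels = [], []
    for idx, d in enumerate(class_dirs):
        for img_path in sorted(d.iterdir()):
            if img_path.suffix.lower() not in (".png", ".tif", ".tiff", ".jpg", ".jpeg"):
                continue
            arr = np.asarray(iio.imread(img_path))[:, :, :3]
            tiles.append(arr.astype(np.uint8))
            labels.append(idx)
    if not tiles:
        raise ValueError(f"no tile images found under {root}")
    return np.stack(tiles), np.asarray(labels, dtype=int), [d.name for d in class_dirs]


def train_classifier(
    spec: ClassifierSpec,
    train_tiles: np.ndarray,
    train_labels: np.ndarray,
    val_tiles: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    epochs: int = 10,
    batch_size: int = 32,
    lr: float = 2e-3,
    augment: bool = True,
    seed: int = 0,
    init_checkpoint=None,
) -> tuple[TileClassifier, TrainingHistory]:
    """Train a tile classifier; labels are head indices (ignore = last).

    ``init_checkpoint`` warm-starts the convolutional stages from a prior
    run's weights (the head is re-initialized when class counts differ), as
    required by the ``imagenet``/``imagenet+domain`` pretrained modes.
    """
    train_labels = np.asarray(train_labels, dtype=int)
    present = set(np.unique(train_labels).tolist())
    missing = [i for i in range(spec.n_heads) if i not in present]
    if missing:
        raise ValueError(f"classes absent from the training set: {missing}")
    clf = TileClassifier(spec, seed=seed)
    if spec.pretrained_mode != "none":
        if init_checkpoint is None:
            raise ValueError(f"pretrained_mode {spec.pretrained_mode!r} requires an init_checkpoint")
        _warm_start(clf.model, init_checkpoint)
    elif init_checkpoint is not None:
        raise ValueError("init_checkpoint given but pretrained_mode is 'none'")

    x_train = preprocess_tiles(train_tiles, spec.input_px)
    x_val = preprocess_tiles(val_tiles, spec.input_px) if val_tiles is not None and len(val_tiles) else None
    val_labels = np.asarray(val_labels, dtype=int) if val_labels is not None else None
    history = clf.model.fit(
        x_train,
        train_labels,
        x_val,
        val_labels,
        epochs=epochs,
        batch_size=batch_size,
        lr=lr,
        augment=augment,
        seed=seed,
    )
    frame = pd.DataFrame(history)
    if x_val is not None:
        pred = clf.model.predict_proba(x_val).argmax(axis=1)
        confusion = np.zeros((spec.n_heads, spec.n_heads), dtype=int)
        np.add.at(confusion, (val_labels, pred), 1)
        final_acc = float((pred == val_labels).mean())
    else:
        confusion = np.zeros((spec.n_heads, spec.n_heads), dtype=int)
        final_acc = float("nan")
    return clf, TrainingHistory(frame=frame, confusion=confusion, final_val_accuracy=final_acc)


def _warm_start(model: SmallCNN, checkpoint) -> None:
    """Copy weights from a prior checkpoint where shapes match (head may differ)."""
    prior = checkpoint if isinstance(checkpoint, SmallCNN) else SmallCNN.load(checkpoint)
    prior_w = prior.get_weights()
    current = model.get_weights()
    merged = {
        k: (prior_w[k] if k in prior_w and prior_w[k].shape == v.shape else v) for k, v in current.items()
    }
    model.set_weights(merged)
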