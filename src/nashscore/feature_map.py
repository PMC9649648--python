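"""Spatial histological feature maps: per-tile classification over a slide.

Applying a feature's classifier to every tissue tile of a slide yields a
grid of class-probability vectors — the feature map.  Background tiles
(too little tissue) are marked ignore without inference.  A per-tile
weighted score condenses each probability vector to the feature's numeric
scale by renormalizing away the ignore mass; tiles dominated by ignore
mass are flagged missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import TileClassifier
from .tiling import DEFAULT_MIN_TISSUE, SlideImage, TileGrid, build_grid, raster_for_scale

IGNORE_MASS_LIMIT = 0.5
"""A tile whose ignore probability exceeds this is flagged missing."""


@dataclass
class FeatureMap:
    """Grid-aligned classifier output for one slide and one feature."""

    slide_id: str
    feature: str
    class_values: tuple[float, ...]
    probs: np.ndarray  # (rows, cols, K+1); NaN where skipped
    argmax: np.ndarray  # (rows, cols) head index; -1 where skipped
    ignore_mask: np.ndarray  # (rows, cols) bool: skipped or argmax == ignore

    @property
    def shape(self) -> tuple[int, int]:
        return self.argmax.shape

    @property
    def n_classes(self) -> int:
        return len(self.class_values)

    def usable_mask(self) -> np.ndarray:
        """Tiles entering slide aggregation: not ignore and ignore mass <= 0.5."""
        with np.errstate(invalid="ignore"):
            dominated = np.where(np.isnan(self.probs[..., -1]), True, self.probs[..., -1] > IGNORE_MASS_LIMIT)
        return ~self.ignore_mask & ~dominated

    def weighted_scores(self) -> np.ndarray:
        """Per-tile weighted scores; NaN where missing (Fig-4-style map values)."""
        out = np.full(self.shape, np.nan)
        usable = self.usable_mask()
        values = np.asarray(self.class_values)
        for r, c in zip(*np.nonzero(usable)):
            out[r, c] = tile_weighted_score(self.probs[r, c], values)
        return out


def tile_weighted_score(probs: np.ndarray, class_values) -> float:
    """Ignore-renormalized expected class value of one tile.

    The ignore mass is dropped and the numeric-class probabilities are
    renormalized; returns NaN (flagged missing) when the ignore mass
    exceeds 0.5 or all mass sits on ignore.
    """
    probs = np.asarray(probs, dtype=float)
    values = np.asarray(class_values, dtype=float)
    if probs.ndim != 1 or len(probs) != len(values) + 1:
        raise ValueError("expected probabilities over numeric classes plus ignore")
    ignore_mass = probs[-1]
    numeric = probs[:-1]
    total = numeric.sum()
    if ignore_mass > IGNORE_MASS_LIMIT or total <= 0:
        return float("nan")
    return float(np.dot(values, numeric / total))


def map_slide(
    classifier: TileClassifier,
    slide: SlideImage,
    grid: TileGrid | None = None,
    min_tissue: float = DEFAULT_MIN_TISSUE,
    batch: int = 64,
) -> FeatureMap:
    """Classify every tissue tile of the slide at the classifier's scale."""
    spec = classifier.spec
    if grid is None:
        grid = build_grid(slide, spec.scale, tile_px=spec.tile_px)
    if grid.scale != spec.scale:
        raise ValueError(f"grid scale {grid.scale!r} does not match classifier scale {spec.scale!r}")
    raster = raster_for_scale(slide, spec.scale)
    rows, cols = grid.rows, grid.cols
    k1 = spec.n_heads
    probs = np.full((rows, cols, k1), np.nan)
    argmax = np.full((rows, cols), -1, dtype=int)
    ignore_mask = np.ones((rows, cols), dtype=bool)

    tissue_tiles = [
        (r, c, x, y)
        for (r, c, x, y), tf in zip(grid.tiles, grid.tissue_fraction)
        if not (tf == tf and tf < min_tissue)  # NaN tissue fraction -> classify
    ]
    if tissue_tiles:
        batch_imgs = np.stack([raster[y : y + grid.tile_px, x : x + grid.tile_px] for _, _, x, y in tissue_tiles])
        out = classifier.classify_tiles(batch_imgs, batch=batch)
        for (r, c, _, _), p in zip(tissue_tiles, out):
            probs[r, c] = p
            argmax[r, c] = int(np.argmax(p))
            ignore_mask[r, c] = argmax[r, c] == spec.ignore_index
    return FeatureMap(
        slide_id=slide.slide_id,
        feature=spec.feature,
        class_values=spec.scheme.class_values,
        probs=probs,
        argmax=argmax,
        ignore_mask=ignore_mask,
    )


def feature_map_frame(fm: FeatureMap) -> pd.DataFrame:
    """Per-tile rows: row, col, probabilities, argmax, weighted score."""
    rows = []
    weighted = fm.weighted_scores()
    for r in range(fm.shape[0]):
        for c in range(fm.shape[1]):
            rec = {"slide_id": fm.slide_id, "feature": fm.feature, "row": r, "col": c}
            for i in range(fm.n_classes):
                rec[f"p_{i}"] = fm.probs[r, c, i]
            rec["p_ignore"] = fm.probs[r, c, -1]
            rec["argmax"] = fm.argmax[r, c]
            rec["ignore"] = bool(fm.ignore_mask[r, c])
            rec["weighted_score"] = weighted[r, c]
            rows.append(rec)
    return pd.DataFrame(rows)


def export_feature_map(fm: FeatureMap, out_dir) -> tuple[Path, Path]:
    """Write the per-tile CSV and a weighted-score heatmap PNG.

    The heatmap uses a fixed colormap with the color range pinned to the
    feature's full score range for cross-slide comparability; ignore tiles
    are transparent.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{fm.slide_id}_{fm.feature}_feature_map.csv"
    feature_map_frame(fm).to_csv(csv_path, index=False, float_format="%.6f")

    png_path = out_dir / f"{fm.slide_id}_{fm.feature}_feature_map.png"
    weighted = fm.weighted_scores()
    fig, ax = plt.subplots(figsize=(max(fm.shape[1] * 0.5, 2), max(fm.shape[0] * 0.5, 2)))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad(alpha=0.0)
    masked = np.ma.masked_invalid(weighted)
    im = ax.imshow(masked, cmap=cmap, vmin=min(fm.class_values), vmax=max(fm.class_values))
    fig.colorbar(im, ax=ax, label=f"weighted {fm.feature} score")
    ax.set_title(f"{fm.slide_id}: {fm.feature}")
    fig.savefig(png_path, dpi=120, transparent=True, bbox_inches="tight")
    plt.close(fig)
    return csv_path, png_path
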