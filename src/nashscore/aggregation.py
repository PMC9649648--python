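"""Reduce a spatial feature map to the scoring ANN's fixed-length input.

Three families of aggregation features summarize a slide's feature map
(average class probabilities, the average per-tile weighted class, and a
per-class spatial entropy), giving a vector of length 2K+1 for a feature
with K numeric classes.

The per-class entropy is the normalized Shannon entropy of how that
class's probability mass distributes *across tiles*: 0 when the class is
focal (all mass in one tile), 1 when it is diffuse (mass spread uniformly
over all usable tiles).  This captures the spatial-pattern information a
pathologist reads from the distribution of a feature over the biopsy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .feature_map import FeatureMap

LOW_CONFIDENCE_TILES = 5
"""Slides aggregated from fewer usable tiles are flagged low-confidence."""


@dataclass
class SlideFeatureVector:
    """Aggregated input of the scoring ANN for one slide and one feature."""

    slide_id: str
    feature: str
    n_classes: int
    avg_probs: np.ndarray  # (K,) mean renormalized class probabilities
    avg_weighted_class: float
    entropies: np.ndarray  # (K,) normalized spatial entropies in [0, 1]
    n_tiles_used: int

    @property
    def low_confidence(self) -> bool:
        return self.n_tiles_used < LOW_CONFIDENCE_TILES

    @property
    def missing(self) -> bool:
        return self.n_tiles_used == 0

    def vector(self) -> np.ndarray:
        """Length 2K+1: avg_probs, avg_weighted_class, entropies."""
        return np.concatenate([self.avg_probs, [self.avg_weighted_class], self.entropies])

    def to_row(self) -> dict:
        row = {"slide_id": self.slide_id, "feature": self.feature, "n_tiles_used": self.n_tiles_used}
        row.update({f"avg_prob_{i}": self.avg_probs[i] for i in range(self.n_classes)})
        row["avg_weighted"] = self.avg_weighted_class
        row.update({f"entropy_{i}": self.entropies[i] for i in range(self.n_classes)})
        row["low_confidence"] = self.low_confidence
        return row


def _renormalized_tile_probs(fm: FeatureMap) -> np.ndarray:
    """(T, K) ignore-renormalized probabilities of the usable tiles."""
    usable = fm.usable_mask()
    numeric = fm.probs[usable][:, :-1]
    totals = numeric.sum(axis=1, keepdims=True)
    return numeric / totals


def aggregate(fm: FeatureMap) -> SlideFeatureVector:
    """Aggregate a feature map; order-invariant in the tiles.

    Slides with zero usable tiles return a vector flagged missing (NaN
    entries) with a warning; callers exclude those from ANN training.
    """
    k = fm.n_classes
    tile_probs = _renormalized_tile_probs(fm)
    t = tile_probs.shape[0]
    if t == 0:
        warnings.warn(f"slide {fm.slide_id}: no usable tiles for {fm.feature}; flagged missing", stacklevel=2)
        return SlideFeatureVector(
            slide_id=fm.slide_id,
            feature=fm.feature,
            n_classes=k,
            avg_probs=np.full(k, np.nan),
            avg_weighted_class=float("nan"),
            entropies=np.full(k, np.nan),
            n_tiles_used=0,
        )
    avg_probs = tile_probs.mean(axis=0)
    values = np.asarray(fm.class_values, dtype=float)
    weighted = tile_probs @ values
    entropies = np.array([_spatial_entropy(tile_probs[:, c]) for c in range(k)])
    return SlideFeatureVector(
        slide_id=fm.slide_id,
        feature=fm.feature,
        n_classes=k,
        avg_probs=avg_probs,
        avg_weighted_class=float(weighted.mean()),
        entropies=entropies,
        n_tiles_used=t,
    )


def _spatial_entropy(mass: np.ndarray) -> float:
    """Normalized Shannon entropy of a nonnegative mass vector over tiles."""
    t = len(mass)
    total = mass.sum()
    if total <= 0 or t <= 1:
        return 0.0
    q = mass / total
    q = q[q > 0]
    return float(-(q * np.log(q)).sum() / np.log(t))


def class_entropy(fm: FeatureMap, class_index: int) -> float:
    """Normalized spatial entropy of one class's mass over usable tiles.

    ``q_t = p_c(t) / sum_t p_c(t)`` over the T usable tiles;
    ``H_c = -sum q_t ln q_t / ln T`` (0 for T = 1 or zero mass).
    """
    tile_probs = _renormalized_tile_probs(fm)
    if not 0 <= class_index < fm.n_classes:
        raise ValueError(f"class index {class_index} out of range")
    return _spatial_entropy(tile_probs[:, class_index])
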