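"""Histological feature definitions shared across the pipeline.

The four features of the Kleiner/Brunt system are scored per slide on
discrete ordinal scales (ballooning 0-2, lobular inflammation 0-3,
steatosis 0-3, fibrosis 0-4).  At the tile level each feature has its own
class scheme: ballooning and inflammation use small presence/density
schemes, steatosis uses area-fraction bins of 5% width, and fibrosis uses
the five macroscopic stage definitions directly.  Every tile classifier
additionally carries one ``ignore`` class for artifacts and non-liver
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HIGH_MPP = 0.44
"""Pixel pitch (µm/px) of high-resolution tiles (ballooning, inflammation, steatosis)."""

LOW_MPP = 1.32
"""Pixel pitch (µm/px) of low-resolution tiles (fibrosis); 1:3 downscale of high."""

TILE_PX = 299
"""Square tile side in pixels at either scale."""

DOWNSCALE = 3
"""Integer downscale factor between the high- and low-resolution rasters."""

IGNORE = "ignore"

#: upper bound of the per-slide score for each feature
SLIDE_SCORE_MAX = {
    "ballooning": 2,
    "inflammation": 3,
    "steatosis": 3,
    "fibrosis": 4,
}

FEATURES = tuple(SLIDE_SCORE_MAX)

#: steatosis tile-classifier bin edges in percent area; bins are
#: half-open [lo, hi) except the last which is closed at 100.
STEATOSIS_BIN_EDGES = tuple(float(x) for x in list(range(0, 75, 5)) + [100])


def steatosis_bin_index(area_pct: float) -> int:
    """Map a tile vacuole-area percentage to its 5%-wide class bin index."""
    if not 0.0 <= area_pct <= 100.0:
        raise ValueError(f"area percentage out of range: {area_pct}")
    idx = int(np.searchsorted(STEATOSIS_BIN_EDGES, area_pct, side="right")) - 1
    return min(idx, len(STEATOSIS_BIN_EDGES) - 2)


@dataclass(frozen=True)
class FeatureScheme:
    """Tile-level class scheme of one feature's classifier."""

    feature: str
    class_values: tuple[float, ...]  # numeric, strictly increasing
    scale: str  # "high" | "low"
    slide_score_max: int = field(init=False)

    def __post_init__(self) -> None:
        if self.feature not in SLIDE_SCORE_MAX:
            raise ValueError(f"unknown feature {self.feature!r}")
        if list(self.class_values) != sorted(set(self.class_values)):
            raise ValueError("class values must be strictly increasing")
        object.__setattr__(self, "slide_score_max", SLIDE_SCORE_MAX[self.feature])

    @property
    def n_classes(self) -> int:
        """Number of numeric classes (K), excluding ignore."""
        return len(self.class_values)

    @property
    def labels(self) -> tuple:
        """All head labels: numeric classes followed by the ignore class."""
        return self.class_values + (IGNORE,)


def default_scheme(feature: str) -> FeatureScheme:
    if feature == "ballooning":
        return FeatureScheme("ballooning", (0.0, 1.0), "high")
    if feature == "inflammation":
        return FeatureScheme("inflammation", (0.0, 1.0, 2.0), "high")
    if feature == "steatosis":
        k = len(STEATOSIS_BIN_EDGES) - 1
        return FeatureScheme("steatosis", tuple(float(i) for i in range(k)), "high")
    if feature == "fibrosis":
        return FeatureScheme("fibrosis", (0.0, 1.0, 2.0, 3.0, 4.0), "low")
    raise ValueError(f"unknown feature {feature!r}")


def mpp_for_scale(scale: str) -> float:
    if scale == "high":
        return HIGH_MPP
    if scale == "low":
        return LOW_MPP
    raise ValueError(f"unknown scale {scale!r}")
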