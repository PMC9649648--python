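"""Classical (non-deep-learning) image-analysis baselines.

Two quantities are measured directly from pixels: the macrovesicular
steatosis area fraction (bright, low-saturation droplets inside tissue)
and the collagen area fraction via color deconvolution of per-pixel
optical densities onto stain vectors followed by thresholding.  A
rank-based group comparison relates either quantity to pathologist score
groups, as in the collagen-area versus AI-score contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, binary_erosion, binary_fill_holes
from scipy.stats import mannwhitneyu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from statsmodels.stats.multitest import multipletests

from . import palette
from .features import HIGH_MPP
from .rules import (  # noqa: F401  (re-exported: the rules are part of this module's surface)
    kleiner_ballooning_score,
    kleiner_inflammation_score,
    kleiner_steatosis_score,
)
from .tiling import DEFAULT_SATURATION_THRESHOLD, rgb_saturation


def tissue_mask(
    rgb: np.ndarray,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
    block: int = 8,
    min_block_fraction: float = 0.15,
) -> np.ndarray:
    """Tissue mask including unstained droplet interiors.

    Saturated ("stained") pixels are pooled into ``block``-sized cells; a
    cell belongs to tissue when enough of it is stained.  Morphological
    closing and hole filling then absorb fat vacuoles — which are white and
    would otherwise read as glass — into the tissue region, including
    vacuoles touching the raster border.
    """
    sat = rgb_saturation(rgb) > saturation_threshold
    h, w = sat.shape
    hb, wb = -(-h // block), -(-w // block)
    padded = np.zeros((hb * block, wb * block), dtype=bool)
    padded[:h, :w] = sat
    cells = padded.reshape(hb, block, wb, block).mean(axis=(1, 3)) > min_block_fraction
    struct = np.ones((2 * (64 // block) + 1,) * 2, dtype=bool)
    # closing without border erosion (erosion treats outside as tissue)
    dilated = binary_dilation(cells, structure=struct)
    closed = binary_fill_holes(binary_erosion(dilated, structure=struct, border_value=1))
    return np.repeat(np.repeat(closed, block, axis=0), block, axis=1)[:h, :w]


def optical_density(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density OD = -log10((I + 1) / 256)."""
    return palette.optical_density(rgb)


@dataclass
class StainModel:
    """Stain unmixing model: unit OD vectors plus a collagen OD threshold.

    The first vector is the collagen stain, the second the cytoplasm
    counterstain; a third completes the basis (orthogonal complement when
    omitted).  Defaults match the synthetic trichrome-like palette and are
    meant to be overridden per staining batch.
    """

    vectors: np.ndarray = field(default_factory=lambda: np.stack([
        palette.stain_vector(palette.COLLAGEN),
        palette.stain_vector(palette.TISSUE),
    ]))
    od_threshold: float = 0.15

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] not in (2, 3):
            raise ValueError("stain vectors must be a (2-3, 3) matrix")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms < 1e-9):
            raise ValueError("zero-norm stain vector")
        v = v / norms[:, None]
        if v.shape[0] == 2:
            third = np.cross(v[0], v[1])
            n3 = np.linalg.norm(third)
            if n3 < 1e-6:
                raise ValueError("stain vectors are collinear")
            v = np.vstack([v, third / n3])
        if abs(np.linalg.det(v)) < 1e-6:
            raise ValueError("stain matrix is singular")
        if self.od_threshold <= 0:
            raise ValueError("od_threshold must be positive")
        self.vectors = v

    def unmix(self, od: np.ndarray) -> np.ndarray:
        """Least-squares stain concentrations for each pixel's OD triplet."""
        flat = od.reshape(-1, 3)
        pinv = np.linalg.pinv(self.vectors).astype(flat.dtype, copy=False)
        conc = flat @ pinv
        return conc.reshape(*od.shape[:-1], 3)

    def remix(self, concentrations: np.ndarray) -> np.ndarray:
        return np.asarray(concentrations) @ self.vectors


def collagen_area_fraction(
    rgb: np.ndarray,
    stain_model: StainModel | None = None,
    tissue: np.ndarray | None = None,
) -> float:
    """Collagen area percent of tissue, by color deconvolution + threshold."""
    stain_model = stain_model or StainModel()
    if tissue is None:
        tissue = tissue_mask(rgb)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        return float("nan")
    conc = stain_model.unmix(optical_density(rgb))
    collagen = (conc[..., 0] > stain_model.od_threshold) & tissue
    return 100.0 * collagen.sum() / n_tissue


def steatosis_area_fraction(
    rgb: np.ndarray,
    mpp: float = HIGH_MPP,
    min_droplet_um2: float = 25.0,
    min_solidity: float = 0.4,
    cluster_um2: float = 2500.0,
    brightness_threshold: float = 0.92,
    saturation_threshold: float = 0.12,
) -> float:
    """Macrovesicular steatosis area percent of tissue.

    Candidate droplet pixels are bright and unsaturated.  Small connected
    components must additionally be compact (solidity) to count as a
    droplet; components above ``cluster_um2`` are accepted by size alone,
    since confluent steatosis merges droplets into irregular clusters.
    Returns NaN when the image contains no tissue.
    """
    tissue = tissue_mask(rgb)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        return float("nan")
    bright = rgb.max(axis=-1) > brightness_threshold * 255.0
    white = bright & (rgb_saturation(rgb) < saturation_threshold) & tissue
    lab = cc_label(white, connectivity=2)
    min_px = min_droplet_um2 / (mpp**2)
    cluster_px = cluster_um2 / (mpp**2)
    keep = np.zeros(lab.max() + 1, dtype=bool)
    for prop in regionprops(lab):
        if prop.area < min_px:
            continue
        if prop.area >= cluster_px or prop.solidity >= min_solidity:
            keep[prop.label] = True
    droplet = keep[lab]
    return 100.0 * droplet.sum() / n_tissue


def group_comparison(
    values_by_group: dict[int, np.ndarray],
    control_group: int = 0,
    alpha: float = 0.05,
    method: str = "holm",
) -> pd.DataFrame:
    """Rank-sum comparison of each score group against the control group.

    Mann-Whitney U per group versus control, multiplicity-corrected across
    the non-control groups.  The control row carries p = 1 by convention;
    groups of size < 2 are flagged and excluded from testing.
    """
    if control_group not in values_by_group:
        raise ValueError(f"control group {control_group} missing")
    control = np.asarray(values_by_group[control_group], dtype=float)
    if len(control) == 0:
        raise ValueError("control group is empty")
    rows = []
    pvals = []
    test_idx = []
    for i, (group, values) in enumerate(sorted(values_by_group.items())):
        values = np.asarray(values, dtype=float)
        row = {
            "group": group,
            "n": len(values),
            "median": float(np.median(values)) if len(values) else float("nan"),
            "direction": float(np.sign(np.median(values) - np.median(control))) if len(values) else float("nan"),
            "flag": "",
        }
        if group == control_group:
            row["p_raw"] = 1.0
        elif len(values) < 2:
            row["p_raw"] = float("nan")
            row["flag"] = "too_small"
        else:
            row["p_raw"] = float(mannwhitneyu(values, control, alternative="two-sided").pvalue)
            pvals.append(row["p_raw"])
            test_idx.append(i)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["p_corrected"] = df["p_raw"]
    if pvals:
        _, corrected, _, _ = multipletests(pvals, alpha=alpha, method=method)
        df.loc[test_idx, "p_corrected"] = corrected
    df["significant"] = df["p_corrected"] < alpha
    df.loc[df["group"] == control_group, "significant"] = False
    return df
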