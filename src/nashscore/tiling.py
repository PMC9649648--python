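"""Whole-slide TIFF reading and the two-scale non-overlapping tile grids.

Slides enter the pipeline as 8-bit RGB TIFF/BigTIFF rasters at a known
pixel pitch of 0.44 µm/px.  Ballooning, inflammation and steatosis are
classified on "high resolution" 299 px tiles taken directly from that
raster (physical side 299 * 0.44 = 131.56 µm, i.e. ~132 µm); fibrosis on
"low resolution" 299 px tiles cut from a 1:3 area-averaged downscale at
1.32 µm/px (side ~395 µm).  Tiles are adjacent and non-overlapping with a
top-left origin; edge remainders smaller than one tile are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .features import DOWNSCALE, HIGH_MPP, TILE_PX, mpp_for_scale

DEFAULT_MIN_TISSUE = 0.05
DEFAULT_SATURATION_THRESHOLD = 0.08


@dataclass
class SlideImage:
    """An in-memory RGB slide raster with its pixel pitch in µm/px."""

    slide_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    mpp: float

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("expected RGB raster with 3 channels")


@dataclass
class TileGrid:
    """Non-overlapping tile coordinates over one slide at one scale.

    ``tiles`` holds ``(row, col, x_px, y_px)`` in the raster of the grid's
    scale; ``tissue_fraction`` is parallel to ``tiles``.
    """

    slide_id: str
    scale: str  # "high" | "low"
    tile_px: int
    rows: int
    cols: int
    tiles: list[tuple[int, int, int, int]]
    tissue_fraction: list[float] = field(default_factory=list)

    @property
    def mpp(self) -> float:
        return mpp_for_scale(self.scale)

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.tiles, columns=["row", "col", "x_px", "y_px"])
        df.insert(0, "slide_id", self.slide_id)
        df.insert(1, "scale", self.scale)
        df["tissue_fraction"] = self.tissue_fraction
        return df


def _mpp_from_tags(page) -> float | None:
    """Recover µm/px from TIFF resolution tags, if present and sane."""
    tags = page.tags
    xres = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if xres is None or unit is None:
        return None
    num, den = xres.value
    if num == 0 or den == 0:
        return None
    pixels_per_unit = num / den
    unit_name = getattr(unit.value, "name", str(unit.value)).upper()
    if "CENTIMETER" in unit_name:
        um_per_unit = 1e4
    elif "INCH" in unit_name:
        um_per_unit = 25400.0
    else:
        return None
    return um_per_unit / pixels_per_unit


def write_slide_tiff(path, pixels: np.ndarray, mpp: float) -> None:
    """Write an 8-bit RGB TIFF carrying µm/px in its resolution tags."""
    from fractions import Fraction

    pixels = np.ascontiguousarray(pixels, dtype=np.uint8)
    # pixels per centimeter as an exact TIFF rational (uint32/uint32)
    ppcm = Fraction(1e4 / mpp).limit_denominator(99_999)
    res = (ppcm.numerator, ppcm.denominator)
    tifffile.imwrite(
        str(path),
        pixels,
        photometric="rgb",
        resolution=(res, res),
        resolutionunit="CENTIMETER",
        compression="zlib",
    )


def load_slide(path, slide_id: str | None = None, mpp: float | None = None) -> SlideImage:
    """Load a TIFF/BigTIFF slide; ``mpp`` overrides/replaces metadata.

    Raises ``ValueError`` when the file carries no resolution metadata and
    no override is supplied, or when the raster is not RGB.
    """
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        pixels = page.asarray()
        meta_mpp = _mpp_from_tags(page)
    if pixels.ndim == 2 or (pixels.ndim == 3 and pixels.shape[2] == 1):
        raise ValueError(f"expected RGB slide, got grayscale: {path}")
    if pixels.ndim != 3 or pixels.shape[2] < 3:
        raise ValueError(f"expected RGB slide: {path}")
    pixels = pixels[:, :, :3]
    eff_mpp = mpp if mpp is not None else meta_mpp
    if eff_mpp is None:
        raise ValueError(f"no µm/px metadata in {path} and no override given")
    if slide_id is None:
        slide_id = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return SlideImage(slide_id=slide_id, pixels=pixels.astype(np.uint8), mpp=float(eff_mpp))


def downscale_raster(pixels: np.ndarray, factor: int = DOWNSCALE) -> np.ndarray:
    """Area-average integer downscale; trailing remainders are cropped."""
    h, w = pixels.shape[:2]
    h2, w2 = h // factor, w // factor
    cropped = pixels[: h2 * factor, : w2 * factor].astype(np.float32)
    block = cropped.reshape(h2, factor, w2, factor, -1).mean(axis=(1, 3))
    return np.clip(np.rint(block), 0, 255).astype(np.uint8)


def rgb_saturation(rgb: np.ndarray) -> np.ndarray:
    """HSV-style saturation (max-min)/max per pixel, 0 where max = 0."""
    arr = np.asarray(rgb)
    mx = arr.max(axis=-1).astype(np.float32)
    mn = arr.min(axis=-1).astype(np.float32)
    mx_safe = np.maximum(mx, np.float32(1e-6))
    sat = mx - mn
    sat /= mx_safe
    return sat


def tissue_fraction(tile_rgb: np.ndarray, saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD) -> float:
    """Fraction of pixels whose saturation exceeds the threshold.

    Tiles below ``min_tissue`` (default 0.05) are treated as background
    (blank glass) and skipped before CNN inference.
    """
    return float(np.mean(rgb_saturation(tile_rgb) > saturation_threshold))


def raster_for_scale(slide: SlideImage, scale: str) -> np.ndarray:
    """Return the slide raster at the requested scale's pixel pitch."""
    if not np.isclose(slide.mpp, HIGH_MPP, rtol=0.05):
        warnings.warn(
            f"slide {slide.slide_id} mpp {slide.mpp} differs from the expected "
            f"high-resolution pitch {HIGH_MPP}; grids assume a {HIGH_MPP} µm/px raster",
            stacklevel=2,
        )
    if scale == "high":
        return slide.pixels
    if scale == "low":
        return downscale_raster(slide.pixels, DOWNSCALE)
    raise ValueError(f"unknown scale {scale!r}")


def build_grid(
    slide: SlideImage,
    scale: str,
    tile_px: int = TILE_PX,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
    compute_tissue: bool = True,
) -> TileGrid:
    """Tile the slide at the given scale into a non-overlapping grid.

    The number of full tiles is floor(W/tile_px) * floor(H/tile_px) on the
    raster of that scale; partial edge tiles are excluded.
    """
    raster = raster_for_scale(slide, scale)
    h, w = raster.shape[:2]
    rows, cols = h // tile_px, w // tile_px
    if rows == 0 or cols == 0:
        warnings.warn(
            f"slide {slide.slide_id} smaller than one {tile_px} px tile at scale {scale}; empty grid",
            stacklevel=2,
        )
    tiles = [(r, c, c * tile_px, r * tile_px) for r in range(rows) for c in range(cols)]
    grid = TileGrid(slide.slide_id, scale, tile_px, rows, cols, tiles)
    if compute_tissue and tiles:
        # one saturation pass over the raster, then per-tile means
        sat = rgb_saturation(raster[: rows * tile_px, : cols * tile_px]) > saturation_threshold
        per_tile = sat.reshape(rows, tile_px, cols, tile_px).mean(axis=(1, 3))
        grid.tissue_fraction = [float(per_tile[r, c]) for r, c, _, _ in tiles]
    else:
        grid.tissue_fraction = [float("nan")] * len(tiles)
    return grid


def extract_tile(raster: np.ndarray, grid: TileGrid, row: int, col: int) -> np.ndarray:
    x, y = col * grid.tile_px, row * grid.tile_px
    return raster[y : y + grid.tile_px, x : x + grid.tile_px]
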