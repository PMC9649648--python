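"""Procedural synthetic liver histology with exact ground truth.

Generates histology-like tiles, whole slides and cohorts that emulate the
four Kleiner/Brunt features — macrovesicular steatosis (white vacuoles),
lobular inflammation (clusters of small dark-purple cells), hepatocyte
ballooning (enlarged pale cells with a central nucleus) and fibrosis
(blue-green collagen with stage-dependent topology) — on a pink tissue
texture.  Every rendered structure is tracked, so per-tile class labels,
per-slide scores and pixel-exact masks are available as ground truth.

Fibrosis stage topology follows the macroscopic stage definitions:
0 only sparse portal collagen specks, 1 a fine perisinusoidal fiber
speckle (adding well under 1% collagen area), 2 periportal collagen rims,
3 fibrous streaks bridging rims, 4 broad collagen rings enclosing tissue
nodules.  Slide scores derive deterministically from the generative
parameters via the Kleiner threshold rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize

from . import palette
from .features import DOWNSCALE, HIGH_MPP, IGNORE, TILE_PX, steatosis_bin_index
from .rules import (
    kleiner_ballooning_score,
    kleiner_inflammation_score,
    kleiner_steatosis_score,
)
from .tiling import write_slide_tiff

# layer codes of the paint raster (later paints overwrite earlier ones)
L_TISSUE, L_COLLAGEN, L_INFLAM, L_BALLOON, L_NUCLEUS, L_VACUOLE, L_GLASS, L_PEN = range(8)

FIELD_SIDE_UM = 660.0
"""Side of the square region modelling one 200x microscope field (µm)."""

BALLOON_FEW_PER_MM2 = (1.2, 2.8)
BALLOON_MANY_PER_MM2 = (8.0, 14.0)
BALLOON_BURDENS = ("none", "few", "many")

#: generative per-score parameter bands used when sampling cohorts; kept
#: strictly inside the Kleiner rule intervals so a sampled slide's score
#: is unambiguous.
STEATOSIS_FRAC_BY_SCORE = {0: (0.000, 0.040), 1: (0.070, 0.300), 2: (0.360, 0.620), 3: (0.680, 0.820)}
INFLAM_DENSITY_BY_SCORE = {0: (0.0, 0.0), 1: (0.5, 1.7), 2: (2.2, 3.8), 3: (4.4, 8.0)}


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Generative parameters of one synthetic slide."""

    slide_id: str
    width_px: int = 1794
    height_px: int = 1794
    mpp: float = HIGH_MPP
    steatosis_area_frac: float = 0.0
    inflam_foci_per_field: float = 0.0
    ballooning_burden: str = "none"
    fibrosis_class: int = 0
    observer_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < TILE_PX or self.height_px < TILE_PX:
            raise ValueError("slide must be at least one tile in each dimension")
        if not 0.0 <= self.steatosis_area_frac <= 1.0:
            raise ValueError("steatosis_area_frac must lie in [0, 1]")
        if self.inflam_foci_per_field < 0:
            raise ValueError("inflam_foci_per_field must be non-negative")
        if self.ballooning_burden not in BALLOON_BURDENS:
            raise ValueError(f"ballooning_burden must be one of {BALLOON_BURDENS}")
        if self.fibrosis_class not in range(5):
            raise ValueError("fibrosis_class must be in 0..4")
        if self.observer_noise_sd < 0:
            raise ValueError("observer_noise_sd must be non-negative")

    @property
    def n_fields(self) -> float:
        """Number of 200x fields covered by the slide."""
        area_um2 = self.width_px * self.height_px * self.mpp**2
        return area_um2 / FIELD_SIDE_UM**2

    @property
    def area_mm2(self) -> float:
        return self.width_px * self.height_px * (self.mpp / 1000.0) ** 2

    def slide_scores(self) -> dict[str, int]:
        """Discrete per-slide scores implied by the generative parameters."""
        return {
            "ballooning": kleiner_ballooning_score(self.ballooning_burden),
            "inflammation": kleiner_inflammation_score(self.inflam_foci_per_field),
            "steatosis": kleiner_steatosis_score(100.0 * self.steatosis_area_frac),
            "fibrosis": int(self.fibrosis_class),
        }


@dataclass
class GroundTruth:
    """Exact labels of one synthetic slide."""

    per_tile_labels: dict[str, np.ndarray]  # feature -> (rows, cols) int grid
    slide_scores: dict[str, int]
    generative_params: SyntheticSlideSpec


@dataclass
class SlideRender:
    """A rendered slide plus its paint raster and ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    layer: np.ndarray  # (H, W) uint8 paint codes
    ground_truth: GroundTruth
    primitives: list = field(default_factory=list)

    @property
    def vacuole_mask(self) -> np.ndarray:
        return self.layer == L_VACUOLE

    @property
    def collagen_mask(self) -> np.ndarray:
        return self.layer == L_COLLAGEN


@dataclass
class TileRender:
    image: np.ndarray
    label: object  # numeric class index or "ignore"
    layer: np.ndarray
    primitives: list = field(default_factory=list)

    @property
    def vacuole_mask(self) -> np.ndarray:
        return self.layer == L_VACUOLE

    @property
    def collagen_mask(self) -> np.ndarray:
        return self.layer == L_COLLAGEN


# --------------------------------------------------------------------------
# painting primitives
# --------------------------------------------------------------------------
class _Painter:
    """Paints structure codes into a layer raster and keeps a shape ledger."""

    def __init__(self, h: int, w: int, mpp: float, rng: np.random.Generator):
        self.layer = np.zeros((h, w), dtype=np.uint8)
        self.h, self.w, self.mpp = h, w, mpp
        self.rng = rng
        self.primitives: list[dict] = []

    def px(self, um: float) -> float:
        return um / self.mpp

    def _paint(self, rr, cc, code: int) -> int:
        """Set pixels to ``code``; returns how many were not already code."""
        added = int(np.count_nonzero(self.layer[rr, cc] != code))
        self.layer[rr, cc] = code
        return added

    def disk(self, cy: float, cx: float, r_um: float, code: int, kind: str) -> int:
        rr, cc = draw_disk((cy, cx), max(self.px(r_um), 1.0), shape=self.layer.shape)
        self.primitives.append({"kind": kind, "center": (cy, cx), "r_um": r_um})
        return self._paint(rr, cc, code)

    def ellipse(self, cy, cx, ry_um, rx_um, rotation, code, kind) -> int:
        rr, cc = draw_ellipse(
            cy, cx, max(self.px(ry_um), 1.0), max(self.px(rx_um), 1.0), rotation=rotation, shape=self.layer.shape
        )
        self.primitives.append({"kind": kind, "center": (cy, cx), "ry_um": ry_um, "rx_um": rx_um})
        return self._paint(rr, cc, code)

    def annulus(self, cy, cx, r_out_um, thickness_um, code, kind) -> int:
        r_out = max(self.px(r_out_um), 3.0)
        r_in = max(r_out - max(self.px(thickness_um), 1.5), 1.0)
        size = int(np.ceil(r_out)) + 2
        patch = np.zeros((2 * size + 1, 2 * size + 1), dtype=bool)
        rr, cc = draw_disk((size, size), r_out, shape=patch.shape)
        patch[rr, cc] = True
        rr, cc = draw_disk((size, size), r_in, shape=patch.shape)
        patch[rr, cc] = False
        yy, xx = np.nonzero(patch)
        yy = yy + int(round(cy)) - size
        xx = xx + int(round(cx)) - size
        keep = (yy >= 0) & (yy < self.h) & (xx >= 0) & (xx < self.w)
        self.primitives.append({"kind": kind, "center": (cy, cx), "r_out_um": r_out_um, "thickness_um": thickness_um})
        return self._paint(yy[keep], xx[keep], code)

    def bar(self, y0, x0, y1, x1, width_um, code, kind) -> int:
        """Thick line segment from (y0,x0) to (y1,x1)."""
        wpx = max(self.px(width_um), 1.0) / 2.0
        dy, dx = y1 - y0, x1 - x0
        norm = float(np.hypot(dy, dx))
        if norm < 1e-9:
            return self.disk(y0, x0, width_um / 2, code, kind)
        ny, nx = -dx / norm * wpx, dy / norm * wpx
        rr, cc = draw_polygon(
            [y0 + ny, y1 + ny, y1 - ny, y0 - ny],
            [x0 + nx, x1 + nx, x1 - nx, x0 - nx],
            shape=self.layer.shape,
        )
        self.primitives.append({"kind": kind, "from": (y0, x0), "to": (y1, x1), "width_um": width_um})
        return self._paint(rr, cc, code)


def _tissue_texture(
    h: int, w: int, rng: np.random.Generator, base=palette.TISSUE, noise_scale: float = 1.0
) -> np.ndarray:
    """Pink-beige base with multiplicative speckle and low-frequency shading.

    ``noise_scale`` attenuates the per-pixel speckle: a raster emulating an
    n:1 area-average downscale carries 1/n of the original speckle
    amplitude (the low-frequency shading is unaffected by averaging).
    """
    low = resize(
        rng.standard_normal((max(h // 96, 3), max(w // 96, 3)), dtype=np.float32),
        (h, w),
        order=1,
        mode="reflect",
    ).astype(np.float32)
    factor = rng.standard_normal((h, w), dtype=np.float32)
    factor *= 0.045 * noise_scale
    factor += 0.035 * low
    factor += 1.0
    return base.astype(np.float32)[None, None, :] * factor[:, :, None]


def _colorize(painter: _Painter, rng: np.random.Generator, glass_background: bool = False) -> np.ndarray:
    h, w = painter.layer.shape
    # pixels at a coarser pitch than the native scan behave like area
    # averages: their noise shrinks accordingly
    noise_scale = min(HIGH_MPP / painter.mpp, 1.0)
    if glass_background:
        img = palette.GLASS.astype(np.float32)[None, None, :] + 1.5 * noise_scale * rng.standard_normal(
            (h, w, 3), dtype=np.float32
        )
    else:
        img = _tissue_texture(h, w, rng, noise_scale=noise_scale)
    jitter = {
        L_COLLAGEN: (palette.COLLAGEN, 7.0),
        L_INFLAM: (palette.INFLAMMATORY, 8.0),
        L_BALLOON: (palette.BALLOON_CYTOPLASM, 3.0),
        L_NUCLEUS: (palette.NUCLEUS, 6.0),
        L_VACUOLE: (palette.VACUOLE, 2.0),
        L_GLASS: (palette.GLASS, 1.5),
        L_PEN: (palette.PEN_MARK, 6.0),
    }
    for code, (color, sd) in jitter.items():
        mask = painter.layer == code
        n = int(mask.sum())
        if n:
            img[mask] = color.astype(np.float32)[None, :] + sd * noise_scale * rng.standard_normal(
                (n, 3), dtype=np.float32
            )
    np.clip(img, 0, 255, out=img)
    return np.rint(img).astype(np.uint8)


# --------------------------------------------------------------------------
# structure generators
# --------------------------------------------------------------------------
def _place_inflammatory_focus(p: _Painter, cy: float, cx: float) -> None:
    n_dots = int(p.rng.integers(18, 32))
    spread = p.px(12.0)
    for _ in range(n_dots):
        dy, dx = p.rng.normal(0, spread, 2)
        p.disk(cy + dy, cx + dx, p.rng.uniform(1.5, 2.5), L_INFLAM, "inflammatory_cell")
    p.primitives.append({"kind": "focus", "center": (cy, cx)})


def _place_ballooned_cell(p: _Painter, cy: float, cx: float) -> None:
    # hydropic degeneration: swollen cells, clearly larger than hepatocytes
    ry = p.rng.uniform(13.0, 18.0)
    rx = ry * p.rng.uniform(0.8, 1.0)
    p.ellipse(cy, cx, ry, rx, p.rng.uniform(0, np.pi), L_BALLOON, "balloon_cytoplasm")
    p.disk(cy, cx, p.rng.uniform(3.0, 4.5), L_NUCLEUS, "balloon_nucleus")
    p.primitives.append({"kind": "balloon", "center": (cy, cx)})


def _fill_vacuoles(
    p: _Painter,
    target_frac: float,
    region=None,
    avoid: list[tuple[float, float]] | None = None,
    avoid_um: float = 20.0,
) -> int:
    """Add white macrovesicular vacuoles until the area fraction is reached.

    As the remaining deficit shrinks, vacuole radii shrink with it, so the
    realized fraction overshoots the target by at most a few pixels.
    """
    y0, x0, h, w = region if region is not None else (0, 0, p.h, p.w)
    total = h * w
    target_px = target_frac * total
    placed_px = 0
    avoid = avoid or []
    avoid_px = p.px(avoid_um)
    n_structures = 0
    while placed_px < target_px and n_structures < 20000:
        deficit = target_px - placed_px
        r_um = p.rng.uniform(8.0, 20.0)
        r_cap = np.sqrt(deficit / np.pi)
        r_px = min(p.px(r_um), max(r_cap, p.px(2.5)))
        cy, cx = None, None
        for _ in range(40):
            ty = y0 + p.rng.uniform(0, h)
            tx = x0 + p.rng.uniform(0, w)
            # fat does not displace fibrotic collagen bands: keep droplet
            # centers off collagen and away from foci/ballooned cells
            if p.layer[int(ty), int(tx)] == L_COLLAGEN:
                continue
            if all((ty - ay) ** 2 + (tx - ax) ** 2 > avoid_px**2 for ay, ax in avoid):
                cy, cx = ty, tx
                break
        if cy is None:
            cy, cx = y0 + p.rng.uniform(0, h), x0 + p.rng.uniform(0, w)
        ratio = p.rng.uniform(0.75, 1.0)
        rr, cc = draw_ellipse(
            cy, cx, max(r_px, 1.0), max(r_px * ratio, 1.0), rotation=p.rng.uniform(0, np.pi), shape=p.layer.shape
        )
        # clip to the region so per-region area stays exact
        keep = (rr >= y0) & (rr < y0 + h) & (cc >= x0) & (cc < x0 + w)
        added = int(np.count_nonzero(p.layer[rr[keep], cc[keep]] != L_VACUOLE))
        p.layer[rr[keep], cc[keep]] = L_VACUOLE
        p.primitives.append({"kind": "vacuole", "center": (cy, cx), "r_px": r_px})
        placed_px += added
        n_structures += 1
    return placed_px


def sample_fibrosis_targets(fibrosis_class: int, rng: np.random.Generator) -> dict[str, float]:
    """Collagen area-fraction targets per structure family for one slide.

    Stage 0 carries only a variable portal baseline; stage 1 adds a small
    perisinusoidal fiber budget (deliberately below 1% so collagen *area*
    barely moves even though the texture changes); stages 2-4 budget
    progressively more area for rims, bridges and cirrhotic rings.
    """
    base = float(rng.uniform(0.002, 0.028))
    if fibrosis_class == 0:
        return {"base": base}
    if fibrosis_class == 1:
        return {"base": base, "fiber": float(rng.uniform(0.0015, 0.0045))}
    if fibrosis_class == 2:
        return {"base": float(rng.uniform(0.001, 0.003)), "rim_total": float(rng.uniform(0.020, 0.032))}
    if fibrosis_class == 3:
        return {
            "base": float(rng.uniform(0.001, 0.003)),
            "rim_total": float(rng.uniform(0.012, 0.018)),
            "total": float(rng.uniform(0.030, 0.046)),
        }
    return {"base": float(rng.uniform(0.001, 0.003)), "total": float(rng.uniform(0.05, 0.08))}


def _render_fibrosis_region(p: _Painter, region: tuple[int, int, int, int], fibrosis_class: int, targets: dict) -> None:
    """Paint one region's collagen structures for the given stage."""
    y0, x0, h, w = region
    total = h * w
    placed = 0

    def add(fn) -> int:
        nonlocal placed
        placed += fn()
        return placed

    def rand_center(margin_px: float) -> tuple[float, float]:
        m = min(margin_px, h / 2 - 1, w / 2 - 1)
        return y0 + p.rng.uniform(m, h - m), x0 + p.rng.uniform(m, w - m)

    # portal baseline specks (all stages)
    limit = targets["base"] * total
    guard = 0
    while placed < limit and guard < 500:
        cy, cx = rand_center(p.px(10))
        add(lambda: p.disk(cy, cx, p.rng.uniform(8.0, 14.0), L_COLLAGEN, "portal_speck"))
        guard += 1

    if fibrosis_class == 1:
        limit = (targets["base"] + targets["fiber"]) * total
        guard = 0
        while placed < limit and guard < 5000:
            cy, cx = y0 + p.rng.uniform(0, h), x0 + p.rng.uniform(0, w)
            ang = p.rng.uniform(0, np.pi)
            length = p.px(p.rng.uniform(50.0, 90.0)) / 2
            add(
                lambda: p.bar(
                    cy - length * np.sin(ang),
                    cx - length * np.cos(ang),
                    cy + length * np.sin(ang),
                    cx + length * np.cos(ang),
                    p.rng.uniform(4.0, 5.5),
                    L_COLLAGEN,
                    "sinusoidal_fiber",
                )
            )
            guard += 1
        return

    if fibrosis_class in (2, 3):
        rim_centers: list[tuple[float, float]] = []
        limit = (targets["base"] + targets["rim_total"]) * total
        guard = 0
        min_rims = 2 if fibrosis_class == 3 else 1
        while (placed < limit or len(rim_centers) < min_rims) and guard < 200:
            r_out = p.rng.uniform(25.0, 35.0)
            cy, cx = rand_center(p.px(r_out) + 2)
            add(lambda: p.annulus(cy, cx, r_out, p.rng.uniform(3.5, 5.5), L_COLLAGEN, "portal_rim"))
            rim_centers.append((cy, cx))
            guard += 1
        if fibrosis_class == 3:
            limit = targets["total"] * total
            guard = 0
            n_bridges = 0
            while (placed < limit or n_bridges < 1) and guard < 200:
                i, j = p.rng.choice(len(rim_centers), size=2, replace=False)
                (ay, ax), (by, bx) = rim_centers[i], rim_centers[j]
                add(lambda: p.bar(ay, ax, by, bx, p.rng.uniform(3.5, 5.5), L_COLLAGEN, "bridge"))
                n_bridges += 1
                guard += 1
        return

    if fibrosis_class == 4:
        limit = targets["total"] * total
        guard = 0
        n_rings = 0
        while (placed < limit or n_rings < 2) and guard < 200:
            r_out = p.rng.uniform(70.0, 110.0)
            cy, cx = rand_center(p.px(r_out) * 0.7)
            add(lambda: p.annulus(cy, cx, r_out, p.rng.uniform(5.0, 8.0), L_COLLAGEN, "nodule_ring"))
            n_rings += 1
            guard += 1


# --------------------------------------------------------------------------
# tiles
# --------------------------------------------------------------------------
_TILE_CLASSES = {
    "ballooning": (0, 1),
    "inflammation": (0, 1, 2),
    "steatosis": tuple(range(15)),
    "fibrosis": (0, 1, 2, 3, 4),
}


def render_tile(
    feature: str,
    class_label,
    tile_px: int = TILE_PX,
    mpp: float | None = None,
    seed: int = 0,
    background: str = "clean",
) -> TileRender:
    """Render one labelled training tile; deterministic for a fixed seed.

    ``background="clean"`` renders only the labelled feature's morphology.
    ``background="mixed"`` additionally paints random amounts of the *other*
    features (fat vacuoles, inflammatory foci, ballooned cells, collagen
    specks), emulating the mixed pathology of real annotated tiles; the
    label always refers to ``feature`` alone.
    """
    if feature not in _TILE_CLASSES:
        raise ValueError(f"unknown feature {feature!r}")
    if background not in ("clean", "mixed"):
        raise ValueError(f"background must be 'clean' or 'mixed': {background!r}")
    if mpp is None:
        mpp = 1.32 if feature == "fibrosis" else HIGH_MPP
    valid = _TILE_CLASSES[feature]
    if class_label != IGNORE and class_label not in valid:
        raise ValueError(f"invalid class {class_label!r} for feature {feature!r}; valid: {list(valid)} or {IGNORE!r}")
    rng = np.random.default_rng(seed)
    p = _Painter(tile_px, tile_px, mpp, rng)

    if class_label == IGNORE:
        variant = rng.choice(["blank", "edge", "pen"])
        if variant == "edge":
            # tissue fragment covering a minor corner wedge of the tile
            ang = rng.uniform(0, 2 * np.pi)
            ny, nx = np.sin(ang), np.cos(ang)
            yy, xx = np.mgrid[0:tile_px, 0:tile_px]
            frac = rng.uniform(0.10, 0.35)
            proj = (yy - tile_px / 2) * ny + (xx - tile_px / 2) * nx
            cut = np.quantile(proj, frac)
            p.layer[:] = L_GLASS
            p.layer[proj <= cut] = L_TISSUE
            img = _colorize(p, rng)
        elif variant == "pen":
            p.layer[:] = L_GLASS
            y0, x0 = rng.uniform(0, tile_px, 2)
            y1, x1 = rng.uniform(0, tile_px, 2)
            p.bar(y0, x0, y1, x1, rng.uniform(30, 80) * mpp, L_PEN, "pen_mark")
            img = _colorize(p, rng, glass_background=True)
        else:
            p.layer[:] = L_GLASS
            img = _colorize(p, rng, glass_background=True)
        p.primitives.append({"kind": f"ignore_{variant}"})
        return TileRender(image=img, label=IGNORE, layer=p.layer, primitives=p.primitives)

    mixed = background == "mixed"

    # paint in the same order as whole slides: collagen, foci, balloons,
    # vacuoles last (so the rendered vacuole area is exact)
    if feature == "fibrosis":
        targets = sample_fibrosis_targets(class_label, rng)
        _render_fibrosis_region(p, (0, 0, tile_px, tile_px), class_label, targets)
    elif mixed and rng.random() < 0.5:
        bg_cls = int(rng.choice([0, 1, 2]))
        _render_fibrosis_region(p, (0, 0, tile_px, tile_px), bg_cls, sample_fibrosis_targets(bg_cls, rng))

    if feature == "inflammation":
        n_foci = {0: 0, 1: int(rng.integers(1, 3)), 2: int(rng.integers(3, 6))}[class_label]
    elif mixed and rng.random() < 0.4:
        n_foci = int(rng.integers(1, 3))
    else:
        n_foci = 0
    centers: list[tuple[float, float]] = []
    margin = min(p.px(25.0), tile_px / 3)
    for _ in range(n_foci):
        cy, cx = rng.uniform(margin, tile_px - margin), rng.uniform(margin, tile_px - margin)
        _place_inflammatory_focus(p, cy, cx)
        centers.append((cy, cx))

    if feature == "ballooning":
        n_cells = 0 if class_label == 0 else int(rng.integers(1, 4))
    elif mixed and rng.random() < 0.3:
        n_cells = int(rng.integers(1, 3))
    else:
        n_cells = 0
    margin = min(p.px(15.0), tile_px / 3)
    for _ in range(n_cells):
        cy, cx = rng.uniform(margin, tile_px - margin), rng.uniform(margin, tile_px - margin)
        _place_ballooned_cell(p, cy, cx)
        centers.append((cy, cx))

    if feature == "steatosis":
        from .features import STEATOSIS_BIN_EDGES

        lo, hi = STEATOSIS_BIN_EDGES[class_label] / 100.0, STEATOSIS_BIN_EDGES[class_label + 1] / 100.0
        span = hi - lo
        target = rng.uniform(lo + 0.05 * span, hi - 0.15 * span) if span > 0 else lo
        _fill_vacuoles(p, target, avoid=centers, avoid_um=25.0)
    elif mixed and rng.random() < 0.75:
        _fill_vacuoles(p, rng.uniform(0.0, 0.8), avoid=centers, avoid_um=25.0)

    img = _colorize(p, rng)
    return TileRender(image=img, label=class_label, layer=p.layer, primitives=p.primitives)


def generate_tile(feature: str, class_label, tile_px: int = TILE_PX, mpp: float | None = None, seed: int = 0):
    """Render one training tile; returns ``(rgb image, class_label)``."""
    tr = render_tile(feature, class_label, tile_px=tile_px, mpp=mpp, seed=seed)
    return tr.image, tr.label


def render_low_res_tile(
    feature: str, class_label, tile_px: int = TILE_PX, seed: int = 0, background: str = "clean"
) -> TileRender:
    """A low-resolution (1.32 µm/px) tile produced the way the pipeline does.

    Renders the corresponding high-resolution region at 0.44 µm/px, then
    applies the same 1:3 area-average downscale used for whole slides, so
    training tiles match the noise spectrum and anti-aliasing of slide
    tiles exactly.
    """
    from .tiling import downscale_raster

    hi = render_tile(
        feature, class_label, tile_px=tile_px * DOWNSCALE, mpp=HIGH_MPP, seed=seed, background=background
    )
    image = downscale_raster(hi.image, DOWNSCALE)
    # a low-res pixel is collagen/vacuole when the majority of its 3x3
    # high-res block is
    layer = np.zeros(image.shape[:2], dtype=np.uint8)
    for code in (L_COLLAGEN, L_VACUOLE):
        block = (hi.layer == code).reshape(tile_px, DOWNSCALE, tile_px, DOWNSCALE).mean(axis=(1, 3))
        layer[block > 0.5] = code
    return TileRender(image=image, label=hi.label, layer=layer, primitives=hi.primitives)


# --------------------------------------------------------------------------
# slides
# --------------------------------------------------------------------------
def render_slide(spec: SyntheticSlideSpec) -> SlideRender:
    """Render a whole synthetic slide with exact per-tile ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    p = _Painter(h, w, spec.mpp, rng)

    # ---- fibrosis: one topology class per slide, painted per low-res tile region
    low_tile_hi_px = TILE_PX * DOWNSCALE  # side of a low-res tile in the high-res raster
    low_rows = (h // DOWNSCALE) // TILE_PX
    low_cols = (w // DOWNSCALE) // TILE_PX
    targets = sample_fibrosis_targets(spec.fibrosis_class, rng)
    for r in range(low_rows):
        for c in range(low_cols):
            jit = {k: v * rng.uniform(0.9, 1.1) for k, v in targets.items()}
            _render_fibrosis_region(p, (r * low_tile_hi_px, c * low_tile_hi_px, low_tile_hi_px, low_tile_hi_px), spec.fibrosis_class, jit)

    # ---- inflammation foci
    n_foci = int(round(spec.inflam_foci_per_field * spec.n_fields))
    margin = p.px(25.0)
    focus_centers = []
    for _ in range(n_foci):
        cy, cx = rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)
        _place_inflammatory_focus(p, cy, cx)
        focus_centers.append((cy, cx))

    # ---- ballooned cells
    if spec.ballooning_burden == "none":
        n_cells = 0
    elif spec.ballooning_burden == "few":
        n_cells = max(1, int(round(rng.uniform(*BALLOON_FEW_PER_MM2) * spec.area_mm2)))
    else:
        n_cells = max(5, int(round(rng.uniform(*BALLOON_MANY_PER_MM2) * spec.area_mm2)))
    balloon_centers = []
    margin = p.px(15.0)
    for _ in range(n_cells):
        cy, cx = rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)
        _place_ballooned_cell(p, cy, cx)
        balloon_centers.append((cy, cx))

    # ---- vacuoles last, so the rendered white area is exact
    _fill_vacuoles(p, spec.steatosis_area_frac, avoid=focus_centers + balloon_centers)

    image = _colorize(p, rng)

    # ---- per-tile ground-truth labels
    hi_rows, hi_cols = h // TILE_PX, w // TILE_PX
    vac = p.layer == L_VACUOLE
    steat = np.zeros((hi_rows, hi_cols), dtype=int)
    inflam = np.zeros((hi_rows, hi_cols), dtype=int)
    balloon = np.zeros((hi_rows, hi_cols), dtype=int)
    focus_tiles = {}
    for cy, cx in focus_centers:
        key = (int(cy // TILE_PX), int(cx // TILE_PX))
        focus_tiles[key] = focus_tiles.get(key, 0) + 1
    balloon_tiles = {(int(cy // TILE_PX), int(cx // TILE_PX)) for cy, cx in balloon_centers}
    for r in range(hi_rows):
        for c in range(hi_cols):
            frac = float(vac[r * TILE_PX : (r + 1) * TILE_PX, c * TILE_PX : (c + 1) * TILE_PX].mean())
            steat[r, c] = steatosis_bin_index(100.0 * min(frac, 1.0))
            nf = focus_tiles.get((r, c), 0)
            inflam[r, c] = 0 if nf == 0 else (1 if nf <= 2 else 2)
            balloon[r, c] = 1 if (r, c) in balloon_tiles else 0
    fib = np.full((low_rows, low_cols), spec.fibrosis_class, dtype=int)

    gt = GroundTruth(
        per_tile_labels={"steatosis": steat, "inflammation": inflam, "ballooning": balloon, "fibrosis": fib},
        slide_scores=spec.slide_scores(),
        generative_params=spec,
    )
    return SlideRender(image=image, layer=p.layer, ground_truth=gt, primitives=p.primitives)


def generate_slide(spec: SyntheticSlideSpec, out_dir) -> tuple[Path, GroundTruth]:
    """Render a slide and write it as a TIFF with µm/px metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    render = render_slide(spec)
    path = out_dir / f"{spec.slide_id}.tiff"
    write_slide_tiff(path, render.image, spec.mpp)
    return path, render.ground_truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------
def _default_score_mix() -> dict[str, np.ndarray]:
    return {
        "ballooning": np.full(3, 1 / 3),
        "inflammation": np.full(4, 1 / 4),
        "steatosis": np.full(4, 1 / 4),
        "fibrosis": np.full(5, 1 / 5),
    }


def spec_for_scores(
    slide_id: str,
    scores: dict[str, int],
    rng: np.random.Generator,
    width_px: int = 1794,
    height_px: int = 1794,
    observer_noise_sd: float = 0.0,
) -> SyntheticSlideSpec:
    """Draw generative parameters that realize the requested slide scores."""
    lo, hi = STEATOSIS_FRAC_BY_SCORE[scores["steatosis"]]
    steat = float(rng.uniform(lo, hi))
    proto = SyntheticSlideSpec(slide_id=slide_id, width_px=width_px, height_px=height_px)
    nf = proto.n_fields
    dlo, dhi = INFLAM_DENSITY_BY_SCORE[scores["inflammation"]]
    if scores["inflammation"] == 0:
        density = 0.0
    else:
        c_lo, c_hi = int(np.ceil(dlo * nf)), int(np.floor(dhi * nf))
        if c_hi < max(c_lo, 1):
            count = max(1, int(round(0.5 * (dlo + dhi) * nf)))
        else:
            count = int(rng.integers(max(c_lo, 1), c_hi + 1))
        density = count / nf
    return SyntheticSlideSpec(
        slide_id=slide_id,
        width_px=width_px,
        height_px=height_px,
        steatosis_area_frac=steat,
        inflam_foci_per_field=density,
        ballooning_burden=BALLOON_BURDENS[scores["ballooning"]],
        fibrosis_class=scores["fibrosis"],
        observer_noise_sd=observer_noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )


def _perturb_score(score: int, s_max: int, sd: float, rng: np.random.Generator) -> int:
    """Observer noise: shift by at most +-1 with probability derived from sd."""
    if sd <= 0:
        return score
    shift = int(np.clip(round(rng.normal(0.0, sd)), -1, 1))
    return int(np.clip(score + shift, 0, s_max))


def generate_cohort(
    n_slides: int,
    out_dir,
    score_mix: dict | None = None,
    observer_noise_sd: float = 0.0,
    seed: int = 0,
    width_px: int = 1794,
    height_px: int = 1794,
    train_frac: float = 0.75,
    write_tile_labels: bool = True,
) -> pd.DataFrame:
    """Generate a cohort of synthetic slides plus a pathologist-score manifest.

    The manifest holds the recorded (possibly noise-perturbed) discrete
    scores, a train/test ``split`` column, and ``true_*`` columns with the
    noiseless ground-truth scores.  Reproducible for a fixed seed.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    from .features import SLIDE_SCORE_MAX

    mix = _default_score_mix()
    for k, v in (score_mix or {}).items():
        if k not in mix:
            raise ValueError(f"unknown feature in score_mix: {k!r}")
        mix[k] = np.asarray(v, dtype=float)
    for feat, probs in mix.items():
        if len(probs) != SLIDE_SCORE_MAX[feat] + 1 or probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"invalid score distribution for {feat}")
    out_dir = Path(out_dir)
    slides_dir = out_dir / "slides"
    slides_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    tile_rows = []
    for i in range(n_slides):
        slide_id = f"synth_{i:04d}"
        scores = {feat: int(rng.choice(len(probs), p=probs)) for feat, probs in mix.items()}
        spec = spec_for_scores(slide_id, scores, rng, width_px, height_px, observer_noise_sd)
        path, gt = generate_slide(spec, slides_dir)
        recorded = {
            feat: _perturb_score(gt.slide_scores[feat], SLIDE_SCORE_MAX[feat], observer_noise_sd, rng)
            for feat in gt.slide_scores
        }
        rows.append(
            {
                "slide_id": slide_id,
                "path": str(path),
                "ballooning": recorded["ballooning"],
                "inflammation": recorded["inflammation"],
                "steatosis": recorded["steatosis"],
                "fibrosis": recorded["fibrosis"],
                "split": "",
                **{f"true_{k}": v for k, v in gt.slide_scores.items()},
            }
        )
        if write_tile_labels:
            for feat, grid in gt.per_tile_labels.items():
                for (r, c), label in np.ndenumerate(grid):
                    tile_rows.append({"slide_id": slide_id, "feature": feat, "row": r, "col": c, "label": int(label)})
    manifest = pd.DataFrame(rows)
    order = rng.permutation(n_slides)
    n_train = int(round(train_frac * n_slides))
    manifest.loc[order[:n_train], "split"] = "train"
    manifest.loc[order[n_train:], "split"] = "test"
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    if write_tile_labels:
        pd.DataFrame(tile_rows).to_csv(out_dir / "tile_labels.csv", index=False)
    return manifest
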