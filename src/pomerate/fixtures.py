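"""Seeded synthetic images with exact ground truth.

Every rating module is exercised against images generated here: trays of
well-separated discs, green apples with brown scald patches of an exact
pixel fraction, iodine-stained cross-sections with dark regions of exact
areas, pears of known chromaticity with red blush patches, and 10-color
cards colinear in (a*, b*). Shapes are discs and blobs, not photorealistic
fruit — the rating arithmetic is shape-agnostic — but colors are chosen in
CIELAB so that the spectral separations the thresholds rely on (>= 40
encoded a* units between healthy and scald / blush modes) hold by
construction.

All synthesis is integer pixel accounting driven by ``numpy``'s seeded
``default_rng``: the same (kind, parameters, seed) always yields the same
bytes, and the recorded truths are exact pixel counts, not approximations.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
from skimage import color as _skcolor

from .raster import RasterImage, rgb_to_lab
from .segment import SegmentedFruit

# CIELAB anchors (L*, a*, b*); encoded a* = a* + 128
GREEN_PEEL = (55.0, -38.0, 35.0)   # encoded a* ~ 90
SCALD_BROWN = (45.0, 32.0, 35.0)   # encoded a* ~ 160
FLESH_BRIGHT = (85.0, 0.0, 25.0)   # encoded L* ~ 217, unstained flesh
STAIN_DARK = (35.0, 10.0, -20.0)   # encoded L* ~ 89, iodine stain
BLUSH_RED = (48.0, 45.0, 28.0)     # encoded a* ~ 173

# card line b* = CARD_SLOPE * a* + CARD_INTERCEPT, greenest -> yellowest
CARD_SLOPE = 1.25
CARD_INTERCEPT = 43.75
CARD_A_RANGE = (-28.0, -4.0)


@dataclasses.dataclass(frozen=True)
class FixtureTruth:
    """Exact ground truth for one synthetic image."""

    kind: str
    seed: int
    masks: tuple[np.ndarray, ...] | None = None      # tray: per-disc, tray order
    count: int | None = None                          # tray
    fraction: float | None = None                     # scald / starch / blush
    patch_mask: np.ndarray | None = None              # scald / blush
    region_areas: tuple[int, ...] | None = None       # starch
    region_masks: tuple[np.ndarray, ...] | None = None
    mean_chromaticity: tuple[float, float] | None = None  # pear
    card_points: np.ndarray | None = None             # card
    line: tuple[float, float] | None = None           # card (slope, intercept)


@lru_cache(maxsize=256)
def chroma_to_rgb8(a: float, b: float, L: float | None = None) -> tuple[int, int, int]:
    """8-bit sRGB for a CIELAB chromaticity, choosing (if unspecified) the
    L* in [20, 95] whose uint8 quantization best round-trips (a*, b*)."""
    candidates = [L] if L is not None else list(np.arange(20.0, 96.0, 1.0))
    best_rgb, best_err = None, np.inf
    for lc in candidates:
        lab = np.array([[[lc, a, b]]], dtype=np.float64)
        rgb8 = np.clip(np.round(_skcolor.lab2rgb(lab) * 255.0), 0, 255).astype(np.uint8)
        back = _skcolor.rgb2lab(rgb8.astype(np.float64) / 255.0)[0, 0]
        err = float(np.hypot(back[1] - a, back[2] - b))
        if err < best_err:
            best_rgb, best_err = tuple(int(v) for v in rgb8[0, 0]), err
    return best_rgb


def _disc_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _nearest_subset(mask: np.ndarray, cy: float, cx: float, n: int,
                    allowed: np.ndarray | None = None) -> np.ndarray:
    """The n pixels of ``mask`` (optionally restricted to ``allowed``)
    nearest to (cy, cx): a compact, contiguous patch of exactly n pixels."""
    pool = mask if allowed is None else (mask & allowed)
    coords = np.argwhere(pool)
    if coords.shape[0] < n:
        raise ValueError("not enough pixels available for requested patch")
    d2 = (coords[:, 0] - cy) ** 2 + (coords[:, 1] - cx) ** 2
    order = np.lexsort((coords[:, 1], coords[:, 0], d2))
    chosen = coords[order[:n]]
    out = np.zeros_like(mask)
    out[chosen[:, 0], chosen[:, 1]] = True
    return out


def _paint(shape: tuple[int, int], regions: list[tuple[np.ndarray, tuple[int, int, int]]]
           ) -> np.ndarray:
    px = np.zeros((*shape, 3), dtype=np.uint8)
    for mask, rgb in regions:
        px[mask] = rgb
    return px


def _lab_noise_image(base_lab: tuple[float, float, float], mask: np.ndarray,
                     patch: np.ndarray, patch_lab: tuple[float, float, float],
                     a_sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Render mask/patch in CIELAB with per-pixel Gaussian noise on a*."""
    h, w = mask.shape
    lab = np.zeros((h, w, 3), dtype=np.float64)
    lab[mask] = base_lab
    lab[patch] = patch_lab
    if a_sigma > 0:
        lab[..., 1] += rng.normal(0.0, a_sigma, size=(h, w))
    rgb = np.clip(np.round(_skcolor.lab2rgb(lab) * 255.0), 0, 255).astype(np.uint8)
    rgb[~mask] = 0
    return rgb


def make_tray(
    n: int, rows: int = 3, cols: int = 6, seed: int = 0, radius: int = 40
) -> tuple[RasterImage, FixtureTruth]:
    """Tray of ``n`` colored discs on black, jittered on a rows x cols grid
    with at least 5 px separation; truth masks are stored in tray order
    (rows top to bottom, right to left within each row)."""
    if n > rows * cols:
        raise ValueError(f"cannot place {n} fruit on a {rows}x{cols} tray")
    rng = np.random.default_rng(seed)
    cell = 2 * radius + 21  # >= 5 px separation with jitter up to 8 px
    margin = radius + 12
    h = 2 * margin + (rows - 1) * cell + 1
    w = 2 * margin + (cols - 1) * cell + 1
    masks: list[np.ndarray] = []
    colors: list[tuple[int, int, int]] = []
    placed = 0
    for r in range(rows):
        for c in range(cols):  # c runs left->right; tray order is right->left
            if placed >= n:
                break
            col_from_right = cols - 1 - c
            cy = margin + r * cell + rng.integers(-8, 9)
            cx = margin + col_from_right * cell + rng.integers(-8, 9)
            masks.append(_disc_mask(h, w, cy, cx, radius))
            colors.append(tuple(int(v) for v in rng.integers(90, 256, size=3)))
            placed += 1
    px = _paint((h, w), list(zip(masks, colors)))
    truth = FixtureTruth(kind="tray", seed=seed, masks=tuple(masks), count=n)
    return RasterImage(px), truth


def make_scald_apple(
    fraction: float, seed: int = 0, radius: int = 80, a_sigma: float = 3.0
) -> tuple[SegmentedFruit, FixtureTruth]:
    """Green apple disc with a contiguous brown scald patch covering exactly
    ``round(fraction * fruit_pixels)`` pixels."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    size = 2 * radius + 9
    cy = cx = size // 2
    fruit = _disc_mask(size, size, cy, cx, radius)
    n_fruit = int(fruit.sum())
    n_patch = int(round(fraction * n_fruit))
    if n_patch > 0:
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0.3, 0.9) * radius
        patch = _nearest_subset(fruit, cy + rho * np.sin(theta), cx + rho * np.cos(theta), n_patch)
    else:
        patch = np.zeros_like(fruit)
    px = _lab_noise_image(GREEN_PEEL, fruit, patch, SCALD_BROWN, a_sigma, rng)
    sub = SegmentedFruit("scald-fixture", 1, RasterImage(px), n_fruit)
    truth = FixtureTruth(
        kind="scald", seed=seed, fraction=n_patch / n_fruit, patch_mask=patch
    )
    return sub, truth


def make_starch_cross_section(
    region_areas: list[int], fruit_radius: int = 80, seed: int = 0
) -> tuple[SegmentedFruit, FixtureTruth]:
    """Bright flesh disc with dark stained regions of the exact requested
    pixel areas, pairwise separated by at least 3 px."""
    rng = np.random.default_rng(seed)
    size = 2 * fruit_radius + 9
    cy = cx = size // 2
    fruit = _disc_mask(size, size, cy, cx, fruit_radius)
    if sum(region_areas) > int(fruit.sum()):
        raise ValueError("requested stained areas exceed the fruit area")
    from scipy import ndimage

    region_masks: list[np.ndarray] = []
    blocked = np.zeros_like(fruit)
    for area in region_areas:
        placed = False
        for _ in range(200):
            theta = rng.uniform(0, 2 * np.pi)
            rho = rng.uniform(0.0, 0.8) * fruit_radius
            ry, rx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
            try:
                cand = _nearest_subset(fruit, ry, rx, area, allowed=~blocked)
            except ValueError:
                continue
            _, ncomp = ndimage.label(cand, structure=np.ones((3, 3), dtype=bool))
            if ncomp != 1:
                continue
            region_masks.append(cand)
            blocked |= ndimage.binary_dilation(
                cand, structure=np.ones((3, 3), dtype=bool), iterations=3
            )
            placed = True
            break
        if not placed:
            raise ValueError(f"cannot pack a stained region of {area} px^2")
    stain = np.zeros_like(fruit)
    for m in region_masks:
        stain |= m
    px = _paint(
        fruit.shape,
        [(fruit, chroma_to_rgb8(FLESH_BRIGHT[1], FLESH_BRIGHT[2], FLESH_BRIGHT[0])),
         (stain, chroma_to_rgb8(STAIN_DARK[1], STAIN_DARK[2], STAIN_DARK[0]))],
    )
    n_fruit = int(fruit.sum())
    sub = SegmentedFruit("starch-fixture", 1, RasterImage(px), n_fruit)
    truth = FixtureTruth(
        kind="starch",
        seed=seed,
        fraction=int(stain.sum()) / n_fruit,
        region_areas=tuple(int(m.sum()) for m in region_masks),
        region_masks=tuple(region_masks),
    )
    return sub, truth


def make_pear(
    chromaticity: tuple[float, float],
    blush_fraction: float = 0.0,
    seed: int = 0,
    scale: int = 60,
) -> tuple[SegmentedFruit, FixtureTruth]:
    """Pear-shaped blob (two overlapping discs) of uniform body color with an
    optional contiguous high-a* blush patch of exact pixel fraction.

    The recorded mean chromaticity is measured from the rendered uint8 image,
    so it is exact for the image actually produced.
    """
    if not (0.0 <= blush_fraction <= 1.0):
        raise ValueError("blush_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = 4 * scale, 3 * scale
    body = _disc_mask(h, w, 2.5 * scale, 1.5 * scale, 1.2 * scale)
    neck = _disc_mask(h, w, 1.2 * scale, 1.5 * scale, 0.7 * scale)
    fruit = body | neck
    n_fruit = int(fruit.sum())
    n_blush = int(round(blush_fraction * n_fruit))
    if n_blush > 0:
        theta = rng.uniform(0, 2 * np.pi)
        patch = _nearest_subset(
            fruit, 2.5 * scale + 0.8 * scale * np.sin(theta),
            1.5 * scale + 0.8 * scale * np.cos(theta), n_blush
        )
    else:
        patch = np.zeros_like(fruit)
    a, b = chromaticity
    px = _paint(
        fruit.shape,
        [(fruit, chroma_to_rgb8(float(a), float(b))),
         (patch, chroma_to_rgb8(BLUSH_RED[1], BLUSH_RED[2], BLUSH_RED[0]))],
    )
    sub = SegmentedFruit("pear-fixture", 1, RasterImage(px), n_fruit)
    lab = rgb_to_lab(sub.image)
    truth = FixtureTruth(
        kind="pear",
        seed=seed,
        fraction=n_blush / n_fruit,
        patch_mask=patch,
        mean_chromaticity=(
            float(lab.a[fruit].mean()), float(lab.b[fruit].mean())
        ),
    )
    return sub, truth


def make_card(
    n: int = 10, noise_sigma: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, FixtureTruth]:
    """``n`` card chromaticities evenly spaced on the reference segment from
    green to yellow, plus optional Gaussian noise; truth stores the exact
    line (slope, intercept)."""
    if n < 2:
        raise ValueError("a card needs at least 2 colors")
    rng = np.random.default_rng(seed)
    a = np.linspace(CARD_A_RANGE[0], CARD_A_RANGE[1], n)
    b = CARD_SLOPE * a + CARD_INTERCEPT
    pts = np.stack([a, b], axis=1)
    if noise_sigma > 0:
        pts = pts + rng.normal(0.0, noise_sigma, size=pts.shape)
    truth = FixtureTruth(
        kind="card", seed=seed, card_points=pts.copy(),
        line=(CARD_SLOPE, CARD_INTERCEPT),
    )
    return pts, truth


def card_to_rgb(card_points: np.ndarray) -> np.ndarray:
    """8-bit RGB rendering of card chromaticities (gamut-checked L* choice)."""
    return np.array(
        [chroma_to_rgb8(float(a), float(b)) for a, b in card_points], dtype=np.uint8
    )
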