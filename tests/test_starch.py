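"""Stain thresholding, region labelling vs a flood-fill oracle, SPI mapping."""

import numpy as np
import pytest

from pomerate.errors import ConfigurationError, DegenerateInputError
from pomerate.fixtures import chroma_to_rgb8, make_starch_cross_section
from pomerate.raster import RasterImage
from pomerate.segment import SegmentedFruit
from pomerate.starch import (
    SpiTable,
    calibrate_stain_threshold,
    filter_small_regions,
    labelled_regions,
    load_spi_table,
    rate_cross_section,
    spi_category,
    stain_mask,
    starch_percent,
)

BRIGHT = chroma_to_rgb8(0.0, 25.0, 85.0)   # encoded L* ~ 217
DARK = chroma_to_rgb8(10.0, -20.0, 35.0)   # encoded L* ~ 89


def flood_fill_oracle(mask, connectivity):
    """Independent region labelling by explicit BFS flood fill."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    seen = np.zeros_like(mask, bool)
    regions = []
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                stack, pix = [(y, x)], []
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    pix.append((cy, cx))
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                regions.append(frozenset(pix))
    return set(regions)


def half_dark_disc(radius=30):
    size = 2 * radius + 5
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    fruit = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    px = np.zeros((size, size, 3), np.uint8)
    px[fruit] = BRIGHT
    dark = fruit & (xx < c)
    px[dark] = DARK
    return SegmentedFruit("half", 1, RasterImage(px), int(fruit.sum())), fruit, dark


# --- stain_mask ----------------------------------------------------------

def test_fully_dark_cross_section_masks_all_fruit():
    size = 65
    px = np.zeros((size, size, 3), np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    fruit = (yy - 32) ** 2 + (xx - 32) ** 2 <= 30**2
    px[fruit] = DARK
    sub = SegmentedFruit("dark", 1, RasterImage(px), int(fruit.sum()))
    mask = stain_mask(sub, l_threshold=120)
    assert (mask == fruit).all()


def test_fully_bright_cross_section_masks_nothing():
    sub, _ = make_starch_cross_section([], fruit_radius=30, seed=2)
    assert stain_mask(sub, l_threshold=120).sum() == 0


def test_half_dark_disc_mask_area_matches_pixel_count():
    sub, fruit, dark = half_dark_disc()
    mask = stain_mask(sub, l_threshold=120)
    assert mask.sum() == dark.sum()
    assert (mask == dark).all()


def test_stain_mask_on_empty_image_is_degenerate():
    sub = SegmentedFruit("x", 1, RasterImage(np.zeros((4, 4, 3), np.uint8)), 1)
    with pytest.raises(DegenerateInputError):
        stain_mask(sub, 120)


# --- labelled_regions ----------------------------------------------------

def test_diagonal_pixels_one_region_conn8_two_conn4():
    mask = np.zeros((4, 4), bool)
    mask[1, 1] = mask[2, 2] = True
    assert len(labelled_regions(mask, 8)) == 1
    assert len(labelled_regions(mask, 4)) == 2
    assert labelled_regions(np.zeros((3, 3), bool)) == []


@pytest.mark.parametrize("connectivity", [4, 8])
def test_labelling_matches_flood_fill_oracle(connectivity, rng):
    for _ in range(100):
        mask = rng.random((50, 50)) < 0.35
        got = {
            frozenset(map(tuple, r.coords.tolist()))
            for r in labelled_regions(mask, connectivity)
        }
        assert got == flood_fill_oracle(mask, connectivity)


# --- filtering and percent -----------------------------------------------

def regions_of_areas(areas):
    out = []
    col = 0
    maxa = max(areas) if areas else 1
    for i, a in enumerate(areas):
        coords = np.array([(r, col) for r in range(a)])
        mask = np.zeros((maxa, len(areas)), bool)
        mask[coords[:, 0], coords[:, 1]] = True
        out.extend(labelled_regions(mask[:, col : col + 1]))
        col += 1
    # simpler: synthesize directly
    from pomerate.starch import StainedRegion

    return [
        StainedRegion(i + 1, np.stack([np.arange(a), np.full(a, i)], axis=1))
        for i, a in enumerate(areas)
    ]


def test_min_area_filter_is_inclusive():
    regions = regions_of_areas([1500, 2000, 2500])
    kept = filter_small_regions(regions, 2000)
    assert sorted(r.area for r in kept) == [2000, 2500]


def test_min_area_filter_edge_cases():
    assert filter_small_regions(regions_of_areas([10, 20]), 100) == []
    regions = regions_of_areas([3, 7])
    assert filter_small_regions(regions, 1) == regions
    with pytest.raises(ValueError):
        filter_small_regions(regions, 0)


def test_percent_arithmetic():
    r = regions_of_areas([5000])
    res = starch_percent(r, 10000)
    assert res.percent_stained == 50.0
    assert res.stained_area == 5000 and res.region_count_retained == 1
    empty = starch_percent([], 10000)
    assert empty.percent_stained == 0.0 and empty.region_count_retained == 0


def test_removing_a_region_decreases_area_exactly():
    regions = regions_of_areas([2500, 3000])
    full = starch_percent(regions, 10**4)
    less = starch_percent(regions[1:], 10**4)
    assert full.stained_area - less.stained_area == 2500


def test_end_to_end_fraction_recovery():
    for seed, areas in [(3, [2500]), (4, [4000]), (5, [2100])]:
        sub, truth = make_starch_cross_section(areas, fruit_radius=60, seed=seed)
        res = rate_cross_section(sub, l_threshold=120)
        assert res.percent_stained == pytest.approx(100 * truth.fraction, abs=0.5)


def test_small_regions_excluded_end_to_end():
    sub, truth = make_starch_cross_section([1500, 2500], fruit_radius=60, seed=6)
    res = rate_cross_section(sub, l_threshold=120)
    assert res.region_count_retained == 1
    assert res.stained_area == 2500


# --- SPI -----------------------------------------------------------------

def spi(rows):
    return SpiTable(tuple(r[0] for r in rows), tuple(float(r[1]) for r in rows))


def test_spi_nearest_and_tie_rule():
    t = spi([("A", 50), ("B", 60), ("C", 80)])
    assert spi_category(62, t) == "B"
    assert spi_category(50, spi([("A", 40), ("B", 60)])) == "A"  # tie -> lower score
    assert spi_category(100, t) == "C"


def test_spi_table_validation():
    with pytest.raises(ConfigurationError):
        SpiTable(("A",), (50.0,))
    with pytest.raises(ConfigurationError):
        SpiTable(("A", "B"), (50.0, 50.0))


def test_bundled_placeholder_tables_load():
    t = load_spi_table("cornell")
    assert len(t.categories) >= 2
    with pytest.raises(ConfigurationError):
        load_spi_table("no_such_card")


# --- calibration ---------------------------------------------------------

def test_calibration_recovers_generating_threshold():
    subs, refs = [], []
    for seed, areas in [(11, [2500]), (12, [3500]), (13, [2100])]:
        sub, truth = make_starch_cross_section(areas, fruit_radius=60, seed=seed)
        subs.append(sub)
        refs.append(100 * truth.fraction)
    # stain encoded L* ~ 89, flesh ~ 217: any threshold between recovers refs
    t = calibrate_stain_threshold(subs, refs, candidates=range(60, 240, 2))
    assert 90 <= t <= 216


def test_calibration_all_bright_zero_refs_returns_lowest():
    subs = [make_starch_cross_section([], fruit_radius=30, seed=s)[0] for s in (1, 2, 3)]
    assert calibrate_stain_threshold(subs, [0, 0, 0], candidates=range(0, 80)) == 0


def test_calibration_single_candidate_and_length_mismatch():
    subs = [make_starch_cross_section([], fruit_radius=30, seed=s)[0] for s in (1, 2, 3)]
    assert calibrate_stain_threshold(subs, [0, 0, 0], candidates=[42]) == 42
    with pytest.raises(ValueError):
        calibrate_stain_threshold(subs, [0, 0])
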