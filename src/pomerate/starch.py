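"""Starch clearing from iodine-stained fruit cross-sections.

Lugol's solution stains starch dark blue-black, so the stained area of a
cross-section is a lightness phenomenon: a fruit pixel counts as stained
when its encoded L* (0-255 scale) falls at or below a threshold. Stained
pixels are grouped into connected regions; regions below a minimum area
(default 2,000 px^2, inclusive) are treated as noise and dropped. The
percent stained area is 100 x retained stained area / cross-section area,
and can be mapped onto a user-supplied starch pattern index (SPI) card by
nearest score.

The default lightness thresholds (apple 120, pear 110 on the encoded scale)
are starting points; :func:`calibrate_stain_threshold` grid-searches a
threshold against reference percentages from expert raters.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError
from .raster import encode_l, rgb_to_lab
from .scald import DEFAULT_Y_FLOOR, fruit_pixel_mask
from .segment import SegmentedFruit

DEFAULT_MIN_AREA = 2000
DEFAULT_THRESHOLDS = {"apple": 120, "pear": 110}

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: np.ones((3, 3), dtype=bool),
}


@dataclasses.dataclass(frozen=True)
class StainedRegion:
    """One connected stained region: label, pixel coordinates, area in px^2."""

    label: int
    coords: np.ndarray  # (N, 2) row/col indices

    @property
    def area(self) -> int:
        return int(self.coords.shape[0])


@dataclasses.dataclass(frozen=True)
class StarchResult:
    region_count_retained: int
    stained_area: int
    fruit_area: int
    percent_stained: float
    spi_category: str | None = None


@dataclasses.dataclass(frozen=True)
class SpiTable:
    """Starch pattern index card: category labels with 0-100 starch scores."""

    categories: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ConfigurationError("an SPI table needs at least 2 rows")
        if len(set(self.scores)) != len(self.scores):
            raise ConfigurationError("SPI scores must be unique")


def load_spi_table(source: str | Path) -> SpiTable:
    """Load an SPI table from a CSV with columns (category, score).

    ``source`` is either a file path or the name of a bundled placeholder
    table (``cornell``, ``enza``, ``jonagold``, ``granny_smith``). The
    bundled tables carry evenly spaced scores only; users should replace
    them with scores read off their own card images.
    """
    path = Path(source)
    if not path.exists():
        pkg_file = resources.files("pomerate").joinpath(f"data/spi/{source}.csv")
        if not pkg_file.is_file():
            raise ConfigurationError(f"SPI table not found: {source}")
        with resources.as_file(pkg_file) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    if not {"category", "score"} <= set(df.columns):
        raise ConfigurationError("SPI CSV must have columns: category, score")
    return SpiTable(
        categories=tuple(str(c) for c in df["category"]),
        scores=tuple(float(s) for s in df["score"]),
    )


def stain_mask(
    sub: SegmentedFruit,
    l_threshold: float,
    y_floor: int = DEFAULT_Y_FLOOR,
) -> np.ndarray:
    """Boolean mask of stained pixels: fruit pixels with encoded L* <= threshold."""
    fruit = fruit_pixel_mask(sub, y_floor)
    l_enc = encode_l(rgb_to_lab(sub.image).L)
    return fruit & (l_enc <= l_threshold)


def labelled_regions(mask: np.ndarray, connectivity: int = 8) -> list[StainedRegion]:
    """Maximal connected components of a binary mask (4- or 8-connectivity)."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    regions = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        regions.append(StainedRegion(label=lab, coords=coords))
    return regions


def filter_small_regions(
    regions: Sequence[StainedRegion], min_area: int = DEFAULT_MIN_AREA
) -> list[StainedRegion]:
    """Retain regions with area >= ``min_area`` (inclusive)."""
    if min_area < 1:
        raise ValueError(f"min_area must be >= 1, got {min_area}")
    return [r for r in regions if r.area >= min_area]


def starch_percent(
    regions_retained: Sequence[StainedRegion], fruit_area: int
) -> StarchResult:
    """Percent stained area from the retained regions."""
    if fruit_area < 1:
        raise ValueError("fruit_area must be >= 1")
    stained = sum(r.area for r in regions_retained)
    return StarchResult(
        region_count_retained=len(regions_retained),
        stained_area=stained,
        fruit_area=fruit_area,
        percent_stained=100.0 * stained / fruit_area,
    )


def spi_category(percent: float, table: SpiTable) -> str:
    """SPI category whose score is nearest to ``percent``; ties take the
    category with the lower score."""
    best = min(
        zip(table.scores, table.categories),
        key=lambda sc: (abs(percent - sc[0]), sc[0]),
    )
    return best[1]


def rate_cross_section(
    sub: SegmentedFruit,
    l_threshold: float | None = None,
    fruit: str = "apple",
    min_area: int = DEFAULT_MIN_AREA,
    connectivity: int = 8,
    spi_table: SpiTable | None = None,
    y_floor: int = DEFAULT_Y_FLOOR,
) -> StarchResult:
    """Full starch pipeline for one segmented cross-section."""
    if l_threshold is None:
        try:
            l_threshold = DEFAULT_THRESHOLDS[fruit]
        except KeyError:
            raise ConfigurationError(f"no default threshold for fruit {fruit!r}") from None
    mask = stain_mask(sub, l_threshold, y_floor)
    fruit_area = int(fruit_pixel_mask(sub, y_floor).sum())
    regions = filter_small_regions(labelled_regions(mask, connectivity), min_area)
    result = starch_percent(regions, fruit_area)
    if spi_table is not None:
        result = dataclasses.replace(
            result, spi_category=spi_category(result.percent_stained, spi_table)
        )
    return result


def calibrate_stain_threshold(
    images: Sequence[SegmentedFruit],
    reference_percents: Sequence[float],
    candidates: Sequence[int] | None = None,
    min_area: int = DEFAULT_MIN_AREA,
    connectivity: int = 8,
    y_floor: int = DEFAULT_Y_FLOOR,
) -> int:
    """Grid-search the lightness threshold that best matches reference ratings.

    Minimizes the mean squared error between computed percent stained and
    ``reference_percents`` over candidate thresholds (default 0-255); ties
    return the lowest threshold.
    """
    if len(images) != len(reference_percents):
        raise ValueError("images and reference_percents must have equal length")
    if len(images) < 3:
        raise ValueError("calibration needs at least 3 images")
    if candidates is None:
        candidates = range(256)
    prepared = []
    for sub in images:
        fruit = fruit_pixel_mask(sub, y_floor)
        l_enc = encode_l(rgb_to_lab(sub.image).L)
        prepared.append((fruit, l_enc, int(fruit.sum())))
    refs = np.asarray(reference_percents, dtype=np.float64)
    best_t, best_mse = None, np.inf
    for t in candidates:
        percents = []
        for fruit, l_enc, area in prepared:
            mask = fruit & (l_enc <= t)
            regions = filter_small_regions(labelled_regions(mask, connectivity), min_area)
            percents.append(starch_percent(regions, area).percent_stained)
        mse = float(np.mean((np.asarray(percents) - refs) ** 2))
        if mse < best_mse:
            best_t, best_mse = int(t), mse
    return best_t
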