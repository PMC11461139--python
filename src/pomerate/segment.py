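"""Fruit instance detection and per-fruit sub-image extraction.

A detection backend turns a tray photograph into a list of
:class:`DetectedInstance` (bounding box, full-image binary mask, confidence).
The bundled ``classical`` backend is deterministic: it thresholds
non-background pixels, fills holes, labels connected components and reports
confidence 1.0 per blob. The backend registry also leaves a slot for an
instance-segmentation neural network; such a model plugs in as a callable
returning the same instances, no other code changes.

Detected instances are confidence-filtered and capped (defaults: keep
confidence >= 0.999, at most 18 fruit), ordered the way technicians number a
tray (rows top to bottom, right to left within a row, starting at the top
right corner), and cropped into background-free sub-images named
``<stem>-1``, ``<stem>-2``, ...
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .raster import RasterImage, write_image

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DetectedInstance:
    """One detected fruit: bbox ``(x1, y1, x2, y2)`` (x2/y2 exclusive), a
    full-image boolean mask (authoritative), and a confidence in [0, 1]."""

    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    confidence: float

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.bbox
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate bbox {self.bbox}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x1, y1, x2, y2 = self.bbox
        return ((x1 + x2) / 2.0, (y1 + y2) / 2.0)


@dataclasses.dataclass(frozen=True)
class SegmentedFruit:
    """A single-fruit sub-image with non-fruit pixels zeroed to black."""

    source_image_id: str
    fruit_index: int
    image: RasterImage
    fruit_pixel_count: int

    def __post_init__(self) -> None:
        if self.fruit_index < 1:
            raise ValueError("fruit_index is 1-based")
        if self.fruit_pixel_count < 1:
            raise ValueError("a segmented fruit must contain fruit pixels")

    @property
    def name(self) -> str:
        return f"{self.source_image_id}-{self.fruit_index}"


def classical_backend(
    img: RasterImage,
    background_max: int = 20,
    min_area: int = 500,
) -> list[DetectedInstance]:
    """Deterministic detector for well-separated fruit on a dark background.

    A pixel is background when ``max(R, G, B) < background_max``. Foreground
    holes are filled, 8-connected components are labelled, and blobs smaller
    than ``min_area`` px^2 are dropped. Every instance gets confidence 1.0.
    """
    fg = img.pixels.max(axis=2) >= background_max
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    instances: list[DetectedInstance] = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        mask = labels == lab
        if mask.sum() < min_area:
            continue
        ys, xs = sl
        bbox = (xs.start, ys.start, xs.stop, ys.stop)
        instances.append(DetectedInstance(bbox=bbox, mask=mask, confidence=1.0))
    return instances


BACKENDS: dict[str, Callable[..., list[DetectedInstance]]] = {
    "classical": classical_backend,
}


def detect_instances(
    img: RasterImage, backend: str = "classical", **params
) -> list[DetectedInstance]:
    """Run the named detection backend on a tray image."""
    try:
        fn = BACKENDS[backend]
    except KeyError:
        raise ConfigurationError(
            f"unknown detection backend {backend!r}; available: {sorted(BACKENDS)}"
        ) from None
    return fn(img, **params)


def filter_and_rank(
    instances: Sequence[DetectedInstance],
    min_conf: float = 0.999,
    top_k: int = 18,
) -> list[DetectedInstance]:
    """Keep instances with confidence >= ``min_conf`` (inclusive), sort by
    confidence descending, and truncate to the ``top_k`` best.

    Ties are broken in tray-traversal order: smaller y1 first, then larger x1.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    kept = [i for i in instances if i.confidence >= min_conf]
    kept.sort(key=lambda i: (-i.confidence, i.bbox[1], -i.bbox[0]))
    return kept[:top_k]


def order_tray(instances: Sequence[DetectedInstance]) -> list[DetectedInstance]:
    """Return instances in tray order: numbered 1..n starting at the top
    right corner, rows top to bottom and right to left within a row.

    Rows are found by clustering bbox centers: a gap between consecutive
    sorted center-y values exceeding half the median bbox height starts a
    new row. The result's position i corresponds to tray number i + 1.
    """
    if not instances:
        return []
    heights = [i.bbox[3] - i.bbox[1] for i in instances]
    half_h = float(np.median(heights)) / 2.0
    by_y = sorted(instances, key=lambda i: i.center[1])
    rows: list[list[DetectedInstance]] = [[by_y[0]]]
    for inst in by_y[1:]:
        if inst.center[1] - rows[-1][-1].center[1] > half_h:
            rows.append([inst])
        else:
            rows[-1].append(inst)
    ordered: list[DetectedInstance] = []
    for row in rows:
        ordered.extend(sorted(row, key=lambda i: -i.center[0]))
    return ordered


def extract_subimages(
    img: RasterImage,
    instances: Sequence[DetectedInstance],
    stem: str,
    out_dir: str | Path | None = None,
) -> list[SegmentedFruit]:
    """Crop each (already tray-ordered) instance to its bbox with out-of-mask
    pixels zeroed, naming the results ``stem-1``, ``stem-2``, ...

    Instances with an empty mask are skipped with a logged warning. When
    ``out_dir`` is given each sub-image is also written as ``<name>.png``.
    """
    out: list[SegmentedFruit] = []
    index = 0
    for inst in instances:
        x1, y1, x2, y2 = inst.bbox
        crop_mask = inst.mask[y1:y2, x1:x2]
        count = int(crop_mask.sum())
        if count == 0:
            logger.warning("instance with empty mask in %s skipped", stem)
            continue
        index += 1
        crop = img.pixels[y1:y2, x1:x2].copy()
        crop[~crop_mask] = 0
        fruit = SegmentedFruit(
            source_image_id=stem,
            fruit_index=index,
            image=RasterImage(crop),
            fruit_pixel_count=count,
        )
        if out_dir is not None:
            write_image(fruit.image, Path(out_dir) / f"{fruit.name}.png")
        out.append(fruit)
    return out


def pair_sides(
    side_a: Sequence[SegmentedFruit], side_b: Sequence[SegmentedFruit]
) -> tuple[list[tuple[SegmentedFruit, SegmentedFruit]], list[int]]:
    """Pair two tray-ordered lists of the same physical fruit by tray number.

    The two photos show the same tray with each fruit rotated 180 degrees but
    left in place, so equal tray numbers identify the same fruit. Returns the
    pairs plus the tray numbers present on only one side (also logged).
    """
    a_by_n = {f.fruit_index: f for f in side_a}
    b_by_n = {f.fruit_index: f for f in side_b}
    common = sorted(a_by_n.keys() & b_by_n.keys())
    unmatched = sorted(a_by_n.keys() ^ b_by_n.keys())
    if unmatched:
        logger.warning("tray numbers without a partner side: %s", unmatched)
    return [(a_by_n[n], b_by_n[n]) for n in common], unmatched
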