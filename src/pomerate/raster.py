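"""Core raster plumbing shared by every rating module.

Images are 8-bit RGB throughout. CIELAB values are kept as *signed* floats
(L* in [0, 100], a*/b* signed) so that chromaticity geometry can be done in
the space the color science is defined in; user-facing 0-255 thresholds are
translated with the 8-bit Lab encoding (a*+128, b*+128, L* x 255/100) via
:func:`encode_a` / :func:`encode_l`.

Binary masks are plain boolean numpy arrays with the same spatial shape as
the image they refer to.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage import color as _skcolor


@dataclasses.dataclass(frozen=True)
class RasterImage:
    """An 8-bit, 3-channel RGB raster.

    Attributes
    ----------
    pixels : numpy.ndarray
        ``(height, width, 3)`` uint8 array.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have positive dimensions")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 3


@dataclasses.dataclass(frozen=True)
class LabImage:
    """Per-pixel CIELAB values (signed floats) with the source's spatial dims."""

    lab: np.ndarray  # (H, W, 3) float: L*, a*, b*

    @property
    def L(self) -> np.ndarray:
        return self.lab[..., 0]

    @property
    def a(self) -> np.ndarray:
        return self.lab[..., 1]

    @property
    def b(self) -> np.ndarray:
        return self.lab[..., 2]


@dataclasses.dataclass(frozen=True)
class RatingRecord:
    """One output row of a rating CSV: fruit identity plus module metrics."""

    source_image_id: str
    fruit_index: int
    metrics: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.fruit_index < 1:
            raise ValueError("fruit_index is 1-based and must be >= 1")


def read_image(path: str | Path) -> RasterImage:
    """Read a PNG or JPEG file into an 8-bit RGB raster.

    An alpha channel, if present, is composited over black (each channel is
    scaled by alpha/255) before being dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if "A" in im.getbands() or im.mode in ("P", "LA", "PA"):
                rgba = np.asarray(im.convert("RGBA"), dtype=np.float64)
                alpha = rgba[..., 3:4] / 255.0
                rgb = np.round(rgba[..., :3] * alpha)
                px = np.clip(rgb, 0, 255).astype(np.uint8)
            else:
                px = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    return RasterImage(px)


def write_image(img: RasterImage, path: str | Path) -> None:
    """Write an RGB raster to disk (format inferred from the suffix)."""
    try:
        Image.fromarray(img.pixels, mode="RGB").save(Path(path))
    except OSError as exc:
        raise IOError(f"cannot write image file {path}: {exc}") from exc


def rgb_to_lab(img: RasterImage) -> LabImage:
    """Convert sRGB (D65 white point) to CIELAB with signed a*, b*."""
    return LabImage(_skcolor.rgb2lab(img.pixels))


def rgb_to_ycrcb(img: RasterImage) -> np.ndarray:
    """Full-range ITU-R BT.601 RGB -> YCrCb conversion.

    Returns an ``(H, W, 3)`` float array in channel order (Y, Cr, Cb), each
    clipped to [0, 255]. Black maps to (0, 128, 128) and white to
    (255, 128, 128).
    """
    rgb = img.pixels.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cr = (r - y) * 0.713 + 128.0
    cb = (b - y) * 0.564 + 128.0
    return np.clip(np.stack([y, cr, cb], axis=-1), 0.0, 255.0)


def gaussian_kernel(kernel_size: int = 3) -> np.ndarray:
    """Normalized 2-D Gaussian kernel of odd side ``kernel_size``.

    Sigma follows the convention sigma = 0.3*((k-1)/2 - 1) + 0.8, so the
    default 3x3 kernel has sigma 0.8.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    if kernel_size == 1:
        return np.ones((1, 1))
    sigma = 0.3 * ((kernel_size - 1) * 0.5 - 1.0) + 0.8
    x = np.arange(kernel_size) - (kernel_size - 1) / 2.0
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_smooth(img, kernel_size: int = 3):
    """Smooth with a normalized Gaussian kernel (reflect edge handling).

    Accepts a :class:`RasterImage` (returned as a rounded uint8 raster) or a
    2-D/3-D float array (returned as float). Output dims equal input dims.
    """
    k = gaussian_kernel(kernel_size)
    if isinstance(img, RasterImage):
        out = np.empty_like(img.pixels, dtype=np.float64)
        for c in range(3):
            out[..., c] = ndimage.convolve(
                img.pixels[..., c].astype(np.float64), k, mode="reflect"
            )
        return RasterImage(np.clip(np.round(out), 0, 255).astype(np.uint8))
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        return ndimage.convolve(arr, k, mode="reflect")
    if arr.ndim == 3:
        out = np.empty_like(arr)
        for c in range(arr.shape[2]):
            out[..., c] = ndimage.convolve(arr[..., c], k, mode="reflect")
        return out
    raise ValueError(f"cannot smooth array of ndim {arr.ndim}")


def masked_gaussian_smooth(
    values: np.ndarray, mask: np.ndarray, kernel_size: int = 3
) -> np.ndarray:
    """Gaussian smoothing normalized to a mask.

    Convolves ``values * mask`` and ``mask`` separately and divides, so that
    pixels outside the mask (e.g. the zeroed black background of a segmented
    fruit) contribute nothing to smoothed values inside it. Outside the mask
    the original values are returned unchanged.
    """
    k = gaussian_kernel(kernel_size)
    m = mask.astype(np.float64)
    arr = np.asarray(values, dtype=np.float64)

    def _one(ch: np.ndarray) -> np.ndarray:
        num = ndimage.convolve(ch * m, k, mode="reflect")
        den = ndimage.convolve(m, k, mode="reflect")
        out = ch.copy()
        inside = mask & (den > 0)
        out[inside] = num[inside] / den[inside]
        return out

    if arr.ndim == 2:
        return _one(arr)
    out = np.empty_like(arr)
    for c in range(arr.shape[2]):
        out[..., c] = _one(arr[..., c])
    return out


def encode_a(a: np.ndarray | float):
    """Signed a* (or b*) -> 8-bit encoded scale (value + 128)."""
    return np.clip(np.asarray(a, dtype=np.float64) + 128.0, 0.0, 255.0)


def decode_a(a_encoded: np.ndarray | float):
    """8-bit encoded a*/b* -> signed scale."""
    return np.asarray(a_encoded, dtype=np.float64) - 128.0


def encode_l(l_star: np.ndarray | float):
    """L* in [0, 100] -> 8-bit encoded scale (L* x 255/100)."""
    return np.asarray(l_star, dtype=np.float64) * 255.0 / 100.0


def write_ratings_csv(
    records: Sequence[RatingRecord],
    path: str | Path,
    fieldnames: Iterable[str] | None = None,
) -> None:
    """Write rating records to a CSV file.

    Rows are sorted by (source_image_id, fruit_index) so reruns are
    byte-identical. All records must share one metric schema. ``fieldnames``
    supplies the metric columns when ``records`` is empty (header-only file).
    """
    metric_cols: list[str]
    if records:
        metric_cols = list(records[0].metrics.keys())
        for rec in records:
            if list(rec.metrics.keys()) != metric_cols:
                raise ValueError("records do not share a single metric schema")
    else:
        metric_cols = list(fieldnames or [])
    rows = [
        {"source_image_id": r.source_image_id, "fruit_index": r.fruit_index, **r.metrics}
        for r in sorted(records, key=lambda r: (r.source_image_id, r.fruit_index))
    ]
    df = pd.DataFrame(rows, columns=["source_image_id", "fruit_index", *metric_cols])
    try:
        df.to_csv(Path(path), index=False, encoding="utf-8", lineterminator="\n")
    except OSError as exc:
        raise IOError(f"cannot write CSV file {path}: {exc}") from exc
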