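"""Superficial scald quantification for green apples.

Scald shows as brown necrotic peel, which in CIELAB sits at distinctly
higher a* (green-red axis) than healthy green peel. Per segmented fruit
side the module:

1. removes residual near-black background by thresholding BT.601 luma,
2. smooths RGB inside the fruit mask with a 3x3 Gaussian (mask-normalized,
   so the black background never bleeds into rim pixels),
3. converts to CIELAB and histograms the encoded a* channel (256 bins),
4. picks a threshold from the histogram mode M and occupied range [L, U] as
   t = M + gamma * (U - L)  (gamma defaults to 0.25), placing the cut
   between the healthy-peel mode and the brown tail,
5. classifies fruit pixels with encoded a* > t as scald, re-smooths that
   binary map (again mask-normalized) and re-binarizes at 0.5, and reports
   scald pixels / fruit pixels.

A fruit's final score averages its two sides; the 1-5 technician bin is a
step function of the score (1 = 0%, 2 = 1-25%, 3 = 26-50%, 4 = 51-75%,
5 = 76-100%, with boundaries at the midpoints of the integer-percent gaps).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateInputError
from .raster import (
    RasterImage,
    encode_a,
    masked_gaussian_smooth,
    rgb_to_lab,
    rgb_to_ycrcb,
)
from .segment import SegmentedFruit

DEFAULT_GAMMA = 0.25
DEFAULT_Y_FLOOR = 10


@dataclasses.dataclass(frozen=True)
class ScaldHistogram:
    """Histogram of encoded a* over fruit pixels (256 bins, 0-255).

    ``lower_limit`` / ``upper_limit`` are the lowest / highest occupied bins
    and ``mode`` the fullest bin.
    """

    counts: np.ndarray
    lower_limit: int
    upper_limit: int
    mode: int

    def __post_init__(self) -> None:
        if not (self.lower_limit <= self.mode <= self.upper_limit):
            raise ValueError("histogram must satisfy L <= M <= U")


@dataclasses.dataclass(frozen=True)
class ScaldResult:
    """Two-sided scald rating for one fruit."""

    side_a: float | None
    side_b: float | None
    fruit_score: float
    bin: int
    single_sided: bool = False


def fruit_pixel_mask(sub: SegmentedFruit, y_floor: int = DEFAULT_Y_FLOOR) -> np.ndarray:
    """Boolean mask of fruit pixels: BT.601 luma Y > ``y_floor``.

    Residual near-black background left by segmentation is excluded; an image
    with no pixel above the floor raises :class:`DegenerateInputError`.
    """
    y = rgb_to_ycrcb(sub.image)[..., 0]
    mask = y > y_floor
    if not mask.any():
        raise DegenerateInputError(
            f"{sub.name}: no fruit pixels above luma floor {y_floor}"
        )
    return mask


def _smoothed_encoded_a(
    sub: SegmentedFruit, mask: np.ndarray, kernel_size: int = 3
) -> np.ndarray:
    """Encoded a* of the mask-smoothed sub-image (float, full frame)."""
    rgb = masked_gaussian_smooth(sub.image.pixels.astype(np.float64), mask, kernel_size)
    smoothed = RasterImage(np.clip(np.round(rgb), 0, 255).astype(np.uint8))
    return encode_a(rgb_to_lab(smoothed).a)


def scald_histogram(
    sub: SegmentedFruit,
    y_floor: int = DEFAULT_Y_FLOOR,
    kernel_size: int = 3,
) -> ScaldHistogram:
    """Build the encoded-a* histogram over fruit pixels of one side."""
    mask = fruit_pixel_mask(sub, y_floor)
    a_enc = _smoothed_encoded_a(sub, mask, kernel_size)
    return histogram_from_values(a_enc[mask])


def histogram_from_values(a_encoded: np.ndarray) -> ScaldHistogram:
    """Histogram encoded a* samples into the 256 integer bins."""
    if a_encoded.size == 0:
        raise DegenerateInputError("empty a* sample for histogram")
    bins = np.clip(np.round(a_encoded), 0, 255).astype(np.intp)
    counts = np.bincount(bins, minlength=256)
    occupied = np.nonzero(counts)[0]
    return ScaldHistogram(
        counts=counts,
        lower_limit=int(occupied[0]),
        upper_limit=int(occupied[-1]),
        mode=int(np.argmax(counts)),
    )


def scald_threshold(hist: ScaldHistogram, gamma: float = DEFAULT_GAMMA) -> int:
    """Encoded-a* cut t = M' + gamma * (U - L), rounded and clamped to [M', U].

    M' anchors the healthy-peel mode. Healthy green peel always sits at the
    low-a* end, so M' is the histogram mode M when M lies in the lower half
    of the occupied range; on a mostly-scalded fruit the max bin is the brown
    scald mode itself, and M' falls back to the lower limit L (the greenest
    pixels present) so the cut still lands below the brown tail. With a
    single occupied bin (U == L) the threshold collapses to the mode and the
    whole fruit rates non-scald.
    """
    low, up, m = hist.lower_limit, hist.upper_limit, hist.mode
    anchor = m if (m - low) <= (up - m) else low
    t = anchor + gamma * (up - low)
    return int(np.clip(round(t), anchor, up))


def scald_fraction(
    sub: SegmentedFruit,
    t: float,
    y_floor: int = DEFAULT_Y_FLOOR,
    kernel_size: int = 3,
    return_mask: bool = False,
):
    """Fraction of fruit pixels classified as scald at encoded-a* cut ``t``.

    The binary scald map is re-smoothed (mask-normalized Gaussian) and
    re-binarized at 0.5 to soften the hard threshold before counting.
    """
    mask = fruit_pixel_mask(sub, y_floor)
    a_enc = _smoothed_encoded_a(sub, mask, kernel_size)
    scald = (a_enc > t) & mask
    soft = masked_gaussian_smooth(scald.astype(np.float64), mask, kernel_size)
    scald = (soft >= 0.5) & mask
    frac = float(scald.sum()) / float(mask.sum())
    if return_mask:
        return frac, scald
    return frac


def rate_side(
    sub: SegmentedFruit,
    gamma: float = DEFAULT_GAMMA,
    y_floor: int = DEFAULT_Y_FLOOR,
    kernel_size: int = 3,
) -> float:
    """Scald fraction of one fruit side with the histogram-derived threshold."""
    hist = scald_histogram(sub, y_floor, kernel_size)
    t = scald_threshold(hist, gamma)
    return scald_fraction(sub, t, y_floor, kernel_size)


def rate_fruit(
    side_a_fraction: float | None, side_b_fraction: float | None
) -> tuple[float, bool]:
    """Final fruit score: mean of the two sides.

    If one side is missing the present side is the score and the result is
    flagged single-sided; both missing is an error.
    """
    sides = [s for s in (side_a_fraction, side_b_fraction) if s is not None]
    if not sides:
        raise DegenerateInputError("both sides missing; fruit cannot be rated")
    for s in sides:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"side fraction {s} outside [0, 1]")
    return float(np.mean(sides)), len(sides) == 1


def scald_bin(score: float) -> int:
    """Map a [0, 1] scald score to the 1-5 technician bin.

    Bin 1 is reserved for exactly 0; the remaining integer-percent bin edges
    (25/26%, 50/51%, 75/76%) are resolved at their midpoints.
    """
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score {score} outside [0, 1]")
    if score == 0.0:
        return 1
    if score <= 0.255:
        return 2
    if score <= 0.505:
        return 3
    if score <= 0.755:
        return 4
    return 5


def score_pair(
    side_a: SegmentedFruit | None,
    side_b: SegmentedFruit | None,
    gamma: float = DEFAULT_GAMMA,
    y_floor: int = DEFAULT_Y_FLOOR,
) -> ScaldResult:
    """Rate a fruit from its two sides (either may be missing, not both)."""
    fa = rate_side(side_a, gamma, y_floor) if side_a is not None else None
    fb = rate_side(side_b, gamma, y_floor) if side_b is not None else None
    score, single = rate_fruit(fa, fb)
    return ScaldResult(
        side_a=fa, side_b=fb, fruit_score=score, bin=scald_bin(score), single_sided=single
    )
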