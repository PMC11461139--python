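"""Pear background-color scoring in CIELAB chromaticity space.

A pear's shade-side peel ripens from green toward yellow, tracing a nearly
straight path in the (a*, b*) plane. A 10-level reference color card, with
its colors plotted in that plane, is summarized by an ordinary least-squares
line b* = slope * a* + intercept. The line's intersection with the
horizontal axis (b* = 0) anchors the score 0.0 (greenest) and its intercept
with the vertical axis (a* = 0) anchors 1.0 (yellowest).

A fruit is summarized by its mean chromaticity p = (mean a*, mean b*) over
fruit pixels. Its score is read off at the point q where the ray from the
origin through p crosses the reference line: score = signed ratio
|q - p0| / |p1 - p0| along the line. The perpendicular distance from p to
the line is reported as a diagnostic of how card-like the fruit color is.
Scores beyond the anchors are kept raw and clamped to [0, 1] for binning;
the 10-level card rating is the card color with the nearest projected score.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedScoreError
from .raster import RasterImage, masked_gaussian_smooth, rgb_to_lab
from .scald import DEFAULT_Y_FLOOR, fruit_pixel_mask
from .segment import SegmentedFruit


@dataclasses.dataclass(frozen=True)
class ChromaticityPoint:
    """Mean (a*, b*) of a fruit's pixels, signed CIELAB scale."""

    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b], dtype=np.float64)


@dataclasses.dataclass(frozen=True)
class ReferenceLine:
    """OLS line through the card colors with its axis-intercept anchors.

    ``p0`` is the intersection with b* = 0 (score 0.0), ``p1`` the intercept
    with a* = 0 (score 1.0). ``bin_scores`` are the card colors' own scores
    after projection onto the line, in card order.
    """

    slope: float
    intercept: float
    p0: np.ndarray
    p1: np.ndarray
    bin_scores: np.ndarray

    def line_parameter(self, q: np.ndarray) -> float:
        """Normalized position of an on-line point q: 0 at p0, 1 at p1."""
        d = self.p1 - self.p0
        return float(np.dot(q - self.p0, d) / np.dot(d, d))


@dataclasses.dataclass(frozen=True)
class ColorResult:
    score_raw: float
    score: float
    distance: float
    bin: int | None = None


def mean_chromaticity(
    sub: SegmentedFruit,
    y_floor: int = DEFAULT_Y_FLOOR,
    kernel_size: int = 3,
) -> ChromaticityPoint:
    """Mean signed (a*, b*) over fruit pixels after background removal and
    mask-normalized smoothing (same preprocessing as the scald module)."""
    mask = fruit_pixel_mask(sub, y_floor)
    rgb = masked_gaussian_smooth(sub.image.pixels.astype(np.float64), mask, kernel_size)
    smoothed = RasterImage(np.clip(np.round(rgb), 0, 255).astype(np.uint8))
    lab = rgb_to_lab(smoothed)
    return ChromaticityPoint(
        a=float(lab.a[mask].mean()), b=float(lab.b[mask].mean())
    )


def fit_card_line(card_points: np.ndarray) -> ReferenceLine:
    """Fit the reference line to card chromaticities (in card order, greenest
    to yellowest) by OLS of b* on a*, and score each card color by
    projecting it onto the line."""
    pts = np.asarray(card_points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ConfigurationError("card must be an (n >= 2, 2) array of (a*, b*)")
    a, b = pts[:, 0], pts[:, 1]
    if np.allclose(a, a[0]):
        raise ConfigurationError("card colors are vertical in (a*, b*); cannot fit b on a")
    slope, intercept = np.polyfit(a, b, 1)
    if not np.isfinite(slope) or slope == 0.0 or not np.isfinite(intercept):
        raise ConfigurationError("degenerate reference line (zero or non-finite slope)")
    p0 = np.array([-intercept / slope, 0.0])
    p1 = np.array([0.0, intercept])
    line = ReferenceLine(
        slope=float(slope),
        intercept=float(intercept),
        p0=p0,
        p1=p1,
        bin_scores=np.empty(0),
    )
    # score each card color via its perpendicular foot on the line
    d = p1 - p0
    feet = p0 + np.outer((pts - p0) @ d / (d @ d), d)
    bin_scores = np.array([line.line_parameter(q) for q in feet])
    if not np.all(np.diff(bin_scores) > 0):
        raise ConfigurationError(
            "card colors do not project to strictly increasing scores; "
            "check the card order"
        )
    return dataclasses.replace(line, bin_scores=bin_scores)


def load_card_csv(path: str | Path) -> np.ndarray:
    """Read a card CSV (columns bin_index, R, G, B) into (a*, b*) points in
    bin order."""
    df = pd.read_csv(Path(path), comment="#")
    needed = {"bin_index", "R", "G", "B"}
    if not needed <= set(df.columns):
        raise ConfigurationError(f"card CSV must have columns {sorted(needed)}")
    df = df.sort_values("bin_index")
    rgb = df[["R", "G", "B"]].to_numpy(dtype=np.uint8)[None, :, :]
    lab = rgb_to_lab(RasterImage(rgb)).lab[0]
    return lab[:, 1:3].copy()


def color_score(p: ChromaticityPoint, line: ReferenceLine) -> ColorResult:
    """Score a chromaticity by intersecting the origin->p ray with the line.

    score_raw is the intersection's normalized line position (0 at p0, 1 at
    p1, sign toward p1); score clamps it to [0, 1]. distance is the
    perpendicular distance from p to the line.
    """
    pa, pb = p.a, p.b
    if pa == 0.0 and pb == 0.0:
        raise UndefinedScoreError("chromaticity at the origin has no score")
    denom = pb - line.slope * pa
    if abs(denom) < 1e-12:
        raise UndefinedScoreError("origin ray is parallel to the reference line")
    t = line.intercept / denom
    q = t * p.as_array()
    score_raw = line.line_parameter(q)
    distance = abs(line.slope * pa - pb + line.intercept) / float(
        np.hypot(line.slope, 1.0)
    )
    return ColorResult(
        score_raw=score_raw,
        score=float(np.clip(score_raw, 0.0, 1.0)),
        distance=distance,
    )


def card_bin(score: float, bin_scores: np.ndarray) -> int:
    """1-based card bin with the nearest projected score; ties take the
    lower index."""
    diffs = np.abs(np.asarray(bin_scores, dtype=np.float64) - score)
    # first index within rounding error of the minimum: ties go to the lower bin
    return int(np.argmax(diffs <= diffs.min() + 1e-9)) + 1


def rate_pear(
    sub: SegmentedFruit,
    line: ReferenceLine,
    y_floor: int = DEFAULT_Y_FLOOR,
) -> tuple[ChromaticityPoint, ColorResult]:
    """Full color pipeline for one segmented pear."""
    p = mean_chromaticity(sub, y_floor)
    result = color_score(p, line)
    return p, dataclasses.replace(result, bin=card_bin(result.score, line.bin_scores))


def rate_pear_color(
    sub: SegmentedFruit, line: ReferenceLine, y_floor: int = DEFAULT_Y_FLOOR
) -> ColorResult:
    """Color result only (see :func:`rate_pear`)."""
    return rate_pear(sub, line, y_floor)[1]
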