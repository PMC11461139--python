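"""Red blush coverage on fruit peel.

Blush is counted with a single user-calibrated cut on the encoded a*
channel (signed a* + 128, so the 0-255 slider scale): a fruit pixel is
blush when its encoded a* is strictly greater than the threshold. Fruit
pixels are all pixels that differ from the black background. The percentage
is 100 x blush pixels / fruit pixels.

Calibration is deliberately manual — commercial blush standards vary by
market — and uses three example fruit of increasing blush severity. The
non-interactive path records a chosen threshold directly; the optional
interactive path shows the three images side by side (resized to 500x300
each) under a live threshold slider and persists the final value on exit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw

from .errors import DegenerateInputError
from .raster import RasterImage, encode_a, rgb_to_lab
from .segment import SegmentedFruit

PURPLE = (128, 0, 128)


@dataclasses.dataclass(frozen=True)
class BlushResult:
    fruit_pixels: int
    blush_pixels: int
    percent: float


def _fruit_mask(sub: SegmentedFruit) -> np.ndarray:
    """Fruit pixels are everything that is not pure black background."""
    mask = sub.image.pixels.max(axis=2) > 0
    if not mask.any():
        raise DegenerateInputError(f"{sub.name}: no non-background pixels")
    return mask


def _blush_mask(sub: SegmentedFruit, a_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    fruit = _fruit_mask(sub)
    a_enc = encode_a(rgb_to_lab(sub.image).a)
    return fruit, fruit & (a_enc > a_threshold)


def blush_percent(sub: SegmentedFruit, a_threshold: float) -> BlushResult:
    """Count blush pixels (encoded a* strictly above the threshold) among
    fruit pixels."""
    fruit, blush = _blush_mask(sub, a_threshold)
    n_fruit = int(fruit.sum())
    n_blush = int(blush.sum())
    return BlushResult(
        fruit_pixels=n_fruit,
        blush_pixels=n_blush,
        percent=100.0 * n_blush / n_fruit,
    )


def render_blush_overlay(
    sub: SegmentedFruit, a_threshold: float
) -> tuple[RasterImage, BlushResult]:
    """Copy of the sub-image with blush pixels recolored purple and the
    percentage annotated in the top-left corner."""
    result = blush_percent(sub, a_threshold)
    _, blush = _blush_mask(sub, a_threshold)
    px = sub.image.pixels.copy()
    px[blush] = PURPLE
    im = Image.fromarray(px, mode="RGB")
    draw = ImageDraw.Draw(im)
    draw.text((4, 4), f"{result.percent:.1f}%", fill=(255, 255, 255))
    return RasterImage(np.asarray(im, dtype=np.uint8)), result


def save_blush_threshold(a_threshold: float, config_path: str | Path) -> None:
    """Persist a calibrated threshold to a YAML config file."""
    path = Path(config_path)
    cfg = {}
    if path.exists():
        cfg = yaml.safe_load(path.read_text()) or {}
    cfg.setdefault("blush", {})["a_threshold"] = a_threshold
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_blush_threshold(config_path: str | Path) -> float:
    cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    try:
        return float(cfg["blush"]["a_threshold"])
    except (KeyError, TypeError) as exc:
        raise DegenerateInputError(
            f"no calibrated blush threshold in {config_path}"
        ) from exc


def _calibration_strip(images: list[SegmentedFruit]) -> np.ndarray:
    """Three calibration images resized to 500x300 each and concatenated
    left to right in severity order."""
    panels = [
        np.asarray(
            Image.fromarray(s.image.pixels, mode="RGB").resize((500, 300)),
            dtype=np.uint8,
        )
        for s in images
    ]
    return np.concatenate(panels, axis=1)


def calibrate_blush(
    three_images: list[SegmentedFruit],
    mode: str = "fixed",
    fixed_threshold: float | None = None,
    config_path: str | Path = "pomerate.yaml",
) -> float:
    """Choose and persist the blush a*-threshold from three example fruit.

    ``three_images`` must be exactly three segmented fruit ordered no blush,
    light blush, intense blush. In ``fixed`` mode ``fixed_threshold`` is
    recorded without UI. In ``interactive`` mode a window shows the three
    images with a live-updating blush mask and a 0-255 slider; the chosen
    value is persisted on close. Interactive mode needs a display and
    otherwise fails with a pointer to fixed mode.
    """
    if len(three_images) != 3:
        raise ValueError(f"calibration needs exactly 3 images, got {len(three_images)}")
    if mode == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed mode requires fixed_threshold")
        if not (0 <= fixed_threshold <= 255):
            raise ValueError("threshold must be within 0-255")
        save_blush_threshold(float(fixed_threshold), config_path)
        return float(fixed_threshold)
    if mode != "interactive":
        raise ValueError(f"unknown calibration mode {mode!r}")
    return _calibrate_interactive(three_images, config_path)


def _calibrate_interactive(
    images: list[SegmentedFruit], config_path: str | Path
) -> float:
    import matplotlib

    if matplotlib.get_backend().lower() == "agg":
        raise RuntimeError(
            "interactive blush calibration needs a display; use "
            "mode='fixed' with fixed_threshold instead"
        )
    import matplotlib.pyplot as plt
    from matplotlib.widgets import Slider

    strip = _calibration_strip(images)
    strip_sub = SegmentedFruit(
        source_image_id="calibration",
        fruit_index=1,
        image=RasterImage(strip),
        fruit_pixel_count=max(int((strip.max(axis=2) > 0).sum()), 1),
    )
    fig, ax = plt.subplots(figsize=(12, 3.2))
    plt.subplots_adjust(bottom=0.25)
    state = {"threshold": 128.0}

    def render(threshold: float) -> np.ndarray:
        overlay, _ = render_blush_overlay(strip_sub, threshold)
        return overlay.pixels

    shown = ax.imshow(render(state["threshold"]))
    ax.set_axis_off()
    slider = Slider(
        plt.axes((0.15, 0.08, 0.7, 0.06)), "a* threshold", 0, 255,
        valinit=state["threshold"], valstep=1,
    )

    def on_change(val):
        state["threshold"] = float(val)
        shown.set_data(render(state["threshold"]))
        fig.canvas.draw_idle()

    slider.on_changed(on_change)
    plt.show()
    save_blush_threshold(state["threshold"], config_path)
    return state["threshold"]
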