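"""Core raster operations against independent closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from pomerate.raster import (
    RasterImage,
    RatingRecord,
    gaussian_kernel,
    gaussian_smooth,
    masked_gaussian_smooth,
    read_image,
    rgb_to_lab,
    rgb_to_ycrcb,
    write_ratings_csv,
)

# --- independent oracles -------------------------------------------------

D65 = np.array([0.95047, 1.0, 1.08883])
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)


def srgb_to_lab_oracle(rgb255):
    """Published sRGB (D65) -> XYZ -> CIELAB closed form, coded directly."""
    c = np.asarray(rgb255, dtype=np.float64) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = SRGB_TO_XYZ @ lin
    r = xyz / D65

    def f(t):
        d = 6.0 / 29.0
        return np.where(t > d**3, np.cbrt(t), t / (3 * d**2) + 4.0 / 29.0)

    fr = f(r)
    L = 116.0 * fr[1] - 16.0
    a = 500.0 * (fr[0] - fr[1])
    b = 200.0 * (fr[1] - fr[2])
    return np.array([L, a, b])


def lab_to_srgb_oracle(lab):
    """Inverse CIELAB -> sRGB, implemented only here for round-trip checks."""
    L, a, b = lab
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    d = 6.0 / 29.0

    def finv(t):
        return np.where(t > d, t**3, 3 * d**2 * (t - 4.0 / 29.0))

    xyz = finv(np.array([fx, fy, fz])) * D65
    lin = np.linalg.solve(SRGB_TO_XYZ, xyz)
    c = np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * np.clip(lin, 0, None) ** (1 / 2.4) - 0.055)
    return np.clip(np.round(c * 255.0), 0, 255)


def ycrcb_oracle(rgb255):
    r, g, b = (float(v) for v in rgb255)
    y = 0.299 * r + 0.587 * g + 0.114 * b
    return np.clip(
        np.array([y, (r - y) * 0.713 + 128.0, (b - y) * 0.564 + 128.0]), 0, 255
    )


def one_pixel(rgb):
    return RasterImage(np.array([[rgb]], dtype=np.uint8))


# --- read_image ----------------------------------------------------------

def test_read_image_identity_cases(tmp_path):
    p = tmp_path / "black.png"
    Image.fromarray(np.zeros((2, 2, 3), np.uint8)).save(p)
    img = read_image(p)
    assert img.pixels.shape == (2, 2, 3)
    assert (img.pixels == 0).all()

    p2 = tmp_path / "red.png"
    Image.fromarray(np.array([[[255, 0, 0]]], np.uint8)).save(p2)
    assert tuple(read_image(p2).pixels[0, 0]) == (255, 0, 0)


def test_read_image_composites_alpha_over_black(tmp_path):
    rgba = np.zeros((1, 2, 4), np.uint8)
    rgba[0, 0] = (255, 255, 255, 0)    # fully transparent white -> black
    rgba[0, 1] = (200, 100, 50, 128)   # half transparent -> scaled by 128/255
    p = tmp_path / "alpha.png"
    Image.fromarray(rgba, "RGBA").save(p)
    img = read_image(p)
    assert tuple(img.pixels[0, 0]) == (0, 0, 0)
    expected = tuple(int(round(c * 128 / 255)) for c in (200, 100, 50))
    assert tuple(img.pixels[0, 1]) == expected


def test_read_image_missing_file_names_path(tmp_path):
    with pytest.raises(IOError, match="no_such"):
        read_image(tmp_path / "no_such.png")


def test_read_image_corrupt_file(tmp_path):
    p = tmp_path / "bad.png"
    p.write_bytes(b"not a png at all")
    with pytest.raises(IOError, match="bad.png"):
        read_image(p)


# --- color conversions ---------------------------------------------------

@pytest.mark.parametrize(
    "rgb",
    [(255, 255, 255), (0, 0, 0), (0, 255, 0), (255, 0, 0), (30, 60, 200)],
)
def test_rgb_to_lab_matches_closed_form(rgb):
    got = rgb_to_lab(one_pixel(rgb)).lab[0, 0]
    want = srgb_to_lab_oracle(rgb)
    assert np.allclose(got, want, atol=0.1)


def test_rgb_to_lab_white_and_black_anchors():
    white = rgb_to_lab(one_pixel((255, 255, 255))).lab[0, 0]
    assert abs(white[0] - 100.0) < 0.01
    assert abs(white[1]) < 0.01 and abs(white[2]) < 0.01
    black = rgb_to_lab(one_pixel((0, 0, 0))).lab[0, 0]
    assert np.allclose(black, 0.0, atol=1e-9)


def test_lab_round_trip_within_one_level(rng):
    pixels = rng.integers(0, 256, size=(1000, 3)).astype(np.uint8)
    lab = rgb_to_lab(RasterImage(pixels[None, :, :])).lab[0]
    back = np.array([lab_to_srgb_oracle(v) for v in lab])
    assert np.abs(back - pixels.astype(np.float64)).max() <= 1.0


@pytest.mark.parametrize(
    "rgb,expected",
    [
        ((0, 0, 0), (0.0, 128.0, 128.0)),
        ((255, 255, 255), (255.0, 128.0, 128.0)),
    ],
)
def test_rgb_to_ycrcb_anchors(rgb, expected):
    got = rgb_to_ycrcb(one_pixel(rgb))[0, 0]
    assert np.allclose(got, expected, atol=1e-9)


def test_rgb_to_ycrcb_matches_bt601_matrix(rng):
    for rgb in rng.integers(0, 256, size=(20, 3)):
        got = rgb_to_ycrcb(one_pixel(tuple(rgb)))[0, 0]
        assert np.allclose(got, ycrcb_oracle(rgb), atol=1e-9)


def test_conversions_are_pure(rng):
    px = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
    img = RasterImage(px.copy())
    assert (rgb_to_lab(img).lab == rgb_to_lab(img).lab).all()
    a = rgb_to_lab(img).lab
    b = rgb_to_lab(RasterImage(px.copy())).lab
    assert (a == b).all()


# --- smoothing -----------------------------------------------------------

def test_gaussian_smooth_preserves_constant_image():
    img = RasterImage(np.full((10, 12, 3), 77, np.uint8))
    assert (gaussian_smooth(img, 3).pixels == 77).all()


def test_gaussian_smooth_kernel_one_is_identity(rng):
    px = rng.integers(0, 256, size=(6, 6, 3)).astype(np.uint8)
    assert (gaussian_smooth(RasterImage(px), 1).pixels == px).all()


def test_gaussian_smooth_single_pixel_center_mass():
    arr = np.zeros((9, 9))
    arr[4, 4] = 255.0
    out = gaussian_smooth(arr, 3)
    k = gaussian_kernel(3)
    assert out[4, 4] == pytest.approx(k[1, 1] * 255.0)
    # direct convolution oracle on the 3x3 neighborhood
    assert out[3, 4] == pytest.approx(k[0, 1] * 255.0)
    assert out[3, 3] == pytest.approx(k[0, 0] * 255.0)


def test_gaussian_smooth_rejects_even_kernel():
    with pytest.raises(ValueError):
        gaussian_smooth(np.zeros((4, 4)), 2)


def test_gaussian_smooth_preserves_global_mean(rng):
    arr = rng.random((40, 40))
    # constant-padded: compare interior means (reflect keeps mass near edges)
    sm = gaussian_smooth(arr, 3)
    assert np.isclose(sm.mean(), arr.mean(), rtol=1e-6, atol=1e-6)


def test_masked_smooth_ignores_background():
    arr = np.zeros((10, 10))
    mask = np.zeros((10, 10), bool)
    mask[2:8, 2:8] = True
    arr[mask] = 200.0
    out = masked_gaussian_smooth(arr, mask, 3)
    # plain smoothing would drag mask-edge values toward 0; normalized must not
    assert np.allclose(out[mask], 200.0)


# --- ratings CSV ---------------------------------------------------------

def rec(img, idx, score):
    return RatingRecord(img, idx, {"score": score})


def test_write_ratings_csv_empty_header_only(tmp_path):
    p = tmp_path / "out.csv"
    write_ratings_csv([], p, fieldnames=["score"])
    assert p.read_text() == "source_image_id,fruit_index,score\n"


def test_write_ratings_csv_sorted_and_round_trips(tmp_path):
    p = tmp_path / "out.csv"
    write_ratings_csv([rec("B", 1, 0.5), rec("A", 2, 0.25), rec("A", 1, 1.0)], p)
    df = pd.read_csv(p)
    assert list(df["source_image_id"]) == ["A", "A", "B"]
    assert list(df["fruit_index"]) == [1, 2, 1]
    assert df["score"].tolist() == [1.0, 0.25, 0.5]


def test_write_ratings_csv_rejects_mixed_schema(tmp_path):
    with pytest.raises(ValueError):
        write_ratings_csv(
            [rec("A", 1, 0.5), RatingRecord("A", 2, {"other": 1})],
            tmp_path / "x.csv",
        )


def test_rating_record_requires_one_based_index():
    with pytest.raises(ValueError):
        RatingRecord("A", 0, {})
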