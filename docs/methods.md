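# Methods

This note records the models behind each rating, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic fixtures do and do not establish about real fruit.

## Color representation

Images are 8-bit sRGB; CIELAB conversion assumes the D65 white point.
Internally a\* and b\* are signed floats, so the pear-color geometry lives in
the plane the color science defines. User-facing thresholds follow the
8-bit Lab convention of the OpenCV ecosystem: encoded a\* = a\* + 128,
encoded L\* = L\* × 255/100. The YCrCb conversion used for background
removal is the full-range BT.601 matrix (black → Y 0, white → Y 255); the
studio-swing variant some libraries implement would shift the luma floor.

Gaussian smoothing uses a normalized k×k kernel with σ = 0.3·((k−1)/2 − 1)
+ 0.8 (σ = 0.8 for the default 3×3) and reflect edge handling.

**Mask-normalized smoothing.** Segmented sub-images have a black
background, and black sits at encoded a\* = 128 — *above* typical scald
thresholds. Plain smoothing therefore bleeds background into the fruit rim
and misclassifies a ring of boundary pixels. The rating modules instead
smooth with a mask-normalized Gaussian (convolve value×mask and mask,
divide inside the mask), which uses only fruit pixels. The plain smoother
remains available as a primitive.

## Fruit detection and tray bookkeeping

Detection is a backend contract returning (bbox, full-image binary mask,
confidence). The bundled `classical` backend thresholds non-background
pixels (max(R, G, B) ≥ 20), fills holes, labels 8-connected components,
drops blobs under 500 px², and reports confidence 1.0. It is intended for
well-separated fruit on dark trays and for deterministic testing; an
instance-segmentation neural network slots into the same registry (a
typical configuration for such a model: two classes, ~30 epochs at
learning rate 1e-3), but no weights or training code ship here.

Filtering keeps confidence ≥ 0.999 (inclusive) and caps at the 18
most-confident instances. Tray numbering clusters bbox centers into rows
wherever the vertical gap between successive sorted centers exceeds half
the median bbox height, orders rows top→bottom and instances right→left
within a row, and numbers 1..n from the top right corner. Whether centroids
or bbox centers are used is immaterial for convex fruit; bbox centers are
cheaper and are what is implemented. Two photos of one tray (fruit rotated
180° in place) are paired by equal tray number, so pairing is invariant to
list order.

## Scald

The a\* histogram of the fruit pixels of one side is summarized by its
occupied range [L, U] and its mode M. The threshold is

    t = M′ + γ·(U − L),  clamped to [M′, U],  γ = 0.25 by default,

where M′ = M when M lies in the lower half of [L, U] and M′ = L otherwise.
The fallback encodes the physical asymmetry of the problem: healthy green
peel is always the low-a\* end, so when the histogram's biggest bin sits in
the upper half of the range the fruit is mostly scalded and the max bin is
the brown mode itself; anchoring at M in that case would make high
coverages unreachable (the cut can never fall below the mode it starts
from). Anchoring at the lower limit keeps the cut between the green
remnant and the brown tail across the whole coverage range.

γ trades false scald (too low) against missed scald (too high); on
fixtures with green/brown modes ≥ 40 encoded units apart the estimate is
insensitive to γ across roughly 0.1–0.4. The hard-thresholded binary map
is re-smoothed (mask-normalized) and re-binarized at 0.5, which deletes
isolated noise pixels and regularizes patch boundaries. A single occupied
bin (uniform fruit) yields t = M and a fraction of exactly 0.

Scores average the two sides; a missing side passes the present side
through with a single-sided flag. Bins follow the technician scheme
(1 = 0%, 2 = 1–25%, 3 = 26–50%, 4 = 51–75%, 5 = 76–100%) with bin 1
reserved for exactly zero and the integer-percent boundaries resolved at
their midpoints (0.255, 0.505, 0.755).

## Starch

Stain is treated as a lightness phenomenon — iodine-stained tissue is dark
regardless of hue drift — so stained pixels are fruit pixels with encoded
L\* ≤ threshold (apple 120, pear 110 by default; both are placeholders
pending calibration on real imagery, which the grid-search calibrator
performs against reference percentages, breaking ties toward the lower
threshold). Connected-component labelling (8-connectivity default) replaces
contour tracing; this is an intentional behavioral improvement over
macro-style contour passes that needed a drawn division line to separate
touching contours, and it never merges genuinely separate regions. Regions
under 2,000 px² (inclusive floor: exactly 2,000 is retained) are dropped as
noise. The denominator is all fruit pixels, including any unstained core
cavity. SPI cards are user-editable CSV tables (category, score); the four
bundled tables are placeholders with evenly spaced scores and must be
replaced with scores read off the user's own card.

## Pear color

The card line is fitted by ordinary least squares of b\* on a\* (total least
squares would be the natural swap if card noise were isotropic; for the
narrow, elongated card configurations seen in practice the difference is
far below the card's own bin spacing). The score-0 anchor p0 is the line's
intersection with b\* = 0 and the score-1 anchor p1 its intercept with
a\* = 0; this matches plotting the chromaticity plane with the origin at
the yellow corner. A sample's score is read at the intersection of the
reference line with the ray from the origin through the sample's mean
chromaticity — not at the perpendicular foot — so the score is exactly
invariant to scaling the chromaticity (p and c·p score identically for any
c > 0). Scores beyond the anchors are reported raw and clamped to [0, 1]
for binning. Card bins are assigned by nearest projected card-color score
with ties (within 1e-9, absorbing float rounding) to the lower bin. Samples
at the origin, or on a ray parallel to the line, have no defined score and
are flagged rather than scored.

## Blush

Fruit pixels are all non-black pixels; blush pixels are those with encoded
a\* strictly above the calibrated threshold; the output percentage is blush
over total fruit pixels. No smoothing is applied — blush boundaries are
genuine color edges, and the threshold is user-chosen precisely because
commercial blush standards differ. The interactive calibrator (three
images resized to 500×300, concatenated no-blush → intense, with a 0–255
slider and live overlay) requires a display; the fixed mode is the
scriptable path and both persist the threshold to the config file that the
rating command reads back.

## Synthetic fixtures

Fixtures are discs and two-disc pear blobs, colored in CIELAB and
converted to sRGB through a gamut-checked helper that picks the L\* whose
uint8 quantization best preserves the requested (a\*, b\*). Ground truth is
exact integer pixel accounting: patch and region masks are constructed as
the n nearest available pixels to a seed point, so their pixel counts equal
the requested areas exactly, and recorded mean chromaticities are measured
from the rendered image. Color modes (green peel ≈ 90 encoded a\*, scald
brown ≈ 160, blush red ≈ 173, flesh ≈ 217 encoded L\*, stain ≈ 89) keep ≥
40 units of separation so the default thresholds are exercised rather than
tuned per fixture. Generation is fully deterministic per (kind, parameters,
seed).

What passing on fixtures shows: the pixel accounting, threshold algebra,
geometry, ordering, and legacy mappings are correct, and recovery of known
fractions is well within the stated tolerances (scald ±0.02, starch ±0.5
points, blush ±0.5 points). What it does not show: robustness to uneven
illumination, shadows, lenticels, stems/calyxes, white-balance drift, or
detector failure modes on real trays — fixtures have clean bimodal color
structure by design. Default problem sizes (discs of radius 60–80, ~20,000
fruit pixels; 18–24 fruit trays; 50-fixture recovery sweeps) were chosen as
the smallest sizes at which boundary effects are negligible relative to
the tolerances.

## Known limitations

- Scald is not distinguished from other necrotic disorders or from dark
  pedicel pixels; anything above the a\* cut counts.
- The classical detection backend assumes separable fruit on dark
  backgrounds; touching fruit merge into one component.
- No lighting normalization or color calibration from physical reference
  targets is performed; scores are only as comparable as the imaging
  conditions.
- Starch thresholds default to plausible values but are meant to be
  calibrated per camera and staining protocol.
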