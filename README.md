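# pomerate

Objective, high-resolution quality ratings for pome fruit (apples and
pears) from ordinary RGB photographs, for postharvest researchers and fruit
quality labs that currently rely on visual technician scales. `pomerate`
segments individual fruit from multi-fruit tray photos and rates four
traits, each with a backward-compatible mapping to the legacy scale a
technician would have used:

| trait | continuous output | legacy mapping |
|---|---|---|
| superficial scald | scald fraction in [0, 1] | 1–5 severity bins |
| starch clearing | % iodine-stained area | SPI card category |
| pear background color | 0–1 green→yellow score | 10-level color card bin |
| peel blush | % blush pixels | — |

## The methods in brief

All ratings run on segmented single-fruit sub-images with a black
background, in the CIELAB color space (L\* lightness, a\* green→red, b\*
blue→yellow; user-facing 0–255 thresholds use the 8-bit encoding a\*+128,
L\*·255/100).

**Scald.** Brown necrotic peel sits at higher a\* than healthy green peel.
Per side, fruit pixels (BT.601 luma Y > 10) are smoothed with a 3×3
Gaussian normalized to the fruit mask, their encoded a\* histogram is built,
and scald pixels are those above t = M′ + γ·(U − L), where M′ is the
healthy-peel mode, [L, U] the occupied histogram range, and γ = 0.25. The
binary map is re-smoothed and re-binarized at 0.5; the fruit score averages
its two sides (the tray is photographed twice with each fruit rotated
180°, paired by tray position).

**Starch.** Iodine stains starch dark, so stained pixels are fruit pixels
with encoded L\* ≤ a threshold (apple default 120, pear 110, calibratable
against expert ratings). Connected stained regions under 2,000 px² are
discarded as noise; percent stained area = 100 × retained area / fruit
area, then mapped to the nearest score of a user-supplied SPI card table.

**Pear color.** A 10-color reference card traces a straight line in
(a\*, b\*), fitted by OLS. The line's b\* = 0 intersection anchors score 0.0
(greenest) and its a\* = 0 intercept anchors 1.0 (yellowest). A pear's mean
chromaticity p is scored where the ray from the origin through p crosses
the line; the perpendicular distance from p to the line is a diagnostic.

**Blush.** A single user-calibrated cut on encoded a\*: fruit pixels
strictly above the threshold are blush, reported as a percentage of all
fruit pixels with an annotated purple overlay image.

Detection of fruit in tray photos is a pluggable backend; the bundled
`classical` backend (threshold, fill holes, connected components) handles
well-separated fruit on dark trays deterministically and reports confidence
1.0. Detections are filtered at confidence ≥ 0.999, capped at the 18 best,
and numbered from the tray's top right corner, rows top→bottom and
right→left within a row.

## Worked example

Every capability has a narrative script under `examples/`; all inputs are
generated by the bundled synthetic-fixture module, so they run anywhere.
`python examples/rate_scald.py` prints:

```
side A: estimated 0.202 (generated 0.200)
side B: estimated 0.403 (generated 0.400)
fruit score (mean of sides): 0.302 -> technician bin 3
bins: 1 = 0%, 2 = 1-25%, 3 = 26-50%, 4 = 51-75%, 5 = 76-100%
```

The two sides carry brown patches covering exactly 20% and 40% of their
fruit pixels; the histogram threshold recovers both within half a percent,
and the averaged score 0.302 falls in technician bin 3 (26–50% coverage).
`python examples/rate_pear_color.py` prints, for a pear generated at card
color 3:

```
pear at (a*=-22.68, b*= 15.42): score 0.352, card bin 3, off-line distance 0.01
```

## Command line

The same pipelines are exposed as subcommands for batch directory
processing, each writing a rating CSV plus the resolved configuration used:

```sh
pomerate segment    --input trays/ --output fruit/ --backend classical
pomerate scald      --input fruit/ --output out/ --gamma 0.25
pomerate starch     --input fruit/ --output out/ --fruit apple --spi cornell
pomerate pear-color --input fruit/ --output out/ --card card.csv
pomerate blush calibrate A.png B.png C.png --threshold 150
pomerate blush rate --input fruit/ --output out/ --threshold 150
pomerate fixtures   --kind scald --params '{"fraction": 0.3}' --seed 1 --out fx/
```

## Layout

- `src/pomerate/` — library modules (`segment`, `scald`, `starch`,
  `pear_color`, `blush`, `fixtures`, `raster`, `config`, `cli`)
- `examples/` — one runnable narrative script per capability
- `docs/methods.md` — models, parameters, numerical choices, limitations
- `tests/` — pytest suite, all fixtures generated at test time
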