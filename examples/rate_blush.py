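"""Calibrate a blush threshold and rate blush coverage on synthetic pears.

Blush is counted with a single cut on the encoded a* channel (0-255
slider scale): fruit pixels strictly above the threshold are blush. The
calibration step records the chosen threshold in a config file; rating then
reports pixel counts and the blush percentage per fruit.
"""

import tempfile
from pathlib import Path

import pomerate as pr
from pomerate.blush import load_blush_threshold

trio = [
    pr.make_pear((-15.0, 25.0), blush_fraction=f, seed=s)[0]
    for f, s in [(0.0, 1), (0.15, 2), (0.6, 3)]
]
cfg = Path(tempfile.mkdtemp()) / "pomerate.yaml"
pr.calibrate_blush(trio, mode="fixed", fixed_threshold=150, config_path=cfg)
threshold = load_blush_threshold(cfg)
print(f"calibrated a* threshold: {threshold:g} (persisted in {cfg.name})")

for frac, seed in [(0.0, 11), (0.25, 12), (0.7, 13)]:
    pear, truth = pr.make_pear((-15.0, 25.0), blush_fraction=frac, seed=seed)
    res = pr.blush_percent(pear, threshold)
    print(
        f"generated {100 * truth.fraction:5.1f}% blush -> measured "
        f"{res.percent:5.1f}% ({res.blush_pixels}/{res.fruit_pixels} pixels)"
    )
print("the percentage is blush pixels over all fruit pixels.")
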