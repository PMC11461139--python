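"""Detect fruit on a synthetic tray photo and extract per-fruit sub-images.

Builds an 18-fruit tray, detects each fruit with the classical backend,
applies the default confidence filter (>= 0.999) and top-18 cap, numbers
the fruit the way technicians do (top right corner first, rows top to
bottom, right to left), and crops background-free sub-images.
"""

import pomerate as pr

tray, truth = pr.make_tray(18, rows=3, cols=6, seed=1)
instances = pr.detect_instances(tray, backend="classical")
kept = pr.filter_and_rank(instances)          # min_conf=0.999, top_k=18
ordered = pr.order_tray(kept)
fruits = pr.extract_subimages(tray, ordered, stem="tray")

print(f"detected {len(instances)} instances, kept {len(kept)} after filtering")
for fruit in fruits[:3]:
    print(f"  {fruit.name}: {fruit.fruit_pixel_count} fruit pixels")
print("tray numbers start at the top right corner; fruit 'tray-1' is the")
print("rightmost fruit of the top row, 'tray-6' the leftmost of that row.")
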