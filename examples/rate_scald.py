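"""Rate superficial scald on two synthetic apple sides and bin the average.

Each side is a green disc with a contiguous brown (high-a*) patch of known
pixel fraction. The module histograms the encoded a* channel of the fruit
pixels, cuts at t = M' + 0.25 * (U - L), counts scald pixels, averages the
two sides, and maps the score onto the legacy 1-5 technician bins.
"""

import pomerate as pr

side_a, truth_a = pr.make_scald_apple(0.20, seed=1)
side_b, truth_b = pr.make_scald_apple(0.40, seed=2)

frac_a = pr.rate_side(side_a)
frac_b = pr.rate_side(side_b)
score, single_sided = pr.rate_fruit(frac_a, frac_b)

print(f"side A: estimated {frac_a:.3f} (generated {truth_a.fraction:.3f})")
print(f"side B: estimated {frac_b:.3f} (generated {truth_b.fraction:.3f})")
print(f"fruit score (mean of sides): {score:.3f} -> technician bin {pr.scald_bin(score)}")
print("bins: 1 = 0%, 2 = 1-25%, 3 = 26-50%, 4 = 51-75%, 5 = 76-100%")
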