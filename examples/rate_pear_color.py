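"""Score pear background color against a 10-color reference card.

The card's colors are fitted with an OLS line in (a*, b*) chromaticity
space; the line's b*=0 intersection anchors score 0.0 (greenest) and its
a*=0 intercept anchors 1.0 (yellowest). A pear is scored where the ray from
the origin through its mean chromaticity crosses the line; the perpendicular
distance to the line diagnoses how card-like the fruit color is.
"""

import pomerate as pr

card_points, _ = pr.make_card(n=10, noise_sigma=0.0, seed=1)
line = pr.fit_card_line(card_points)
print(f"reference line: b* = {line.slope:.3f} a* + {line.intercept:.2f}")
print(f"anchors: p0 = {line.p0} (score 0), p1 = {line.p1} (score 1)")

for a, b in [tuple(card_points[2]), (-15.0, 25.0), (-3.0, 40.0)]:
    pear, _ = pr.make_pear((a, b), seed=3)
    point, res = pr.rate_pear(pear, line)
    print(
        f"pear at (a*={point.a:6.2f}, b*={point.b:6.2f}): "
        f"score {res.score:.3f}, card bin {res.bin}, off-line distance {res.distance:.2f}"
    )
print("higher scores mean yellower (riper) pears; large distances flag")
print("colors the card does not really cover.")
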