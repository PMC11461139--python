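"""Quantify iodine-stained area of a synthetic cross-section and map to SPI.

The fixture is a bright flesh disc with dark stained regions of exact pixel
areas. Stained pixels (encoded L* at or below the threshold) are grouped
into connected regions; regions under 2,000 px^2 are treated as noise and
dropped, so the small 1,500 px^2 blob below does not count.
"""

import pomerate as pr
from pomerate.starch import load_spi_table

sub, truth = pr.make_starch_cross_section([1500, 5000], fruit_radius=80, seed=4)
table = load_spi_table("cornell")  # placeholder scores; supply your own card
res = pr.rate_cross_section(sub, l_threshold=120, spi_table=table)

print(f"generated regions: {truth.region_areas} px^2 on {res.fruit_area} px^2 fruit")
print(f"retained regions (>= 2000 px^2): {res.region_count_retained}")
print(f"stained area: {res.stained_area} px^2 -> {res.percent_stained:.2f}% of the cross-section")
print(f"nearest SPI category on the 'cornell' placeholder card: {res.spi_category}")
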