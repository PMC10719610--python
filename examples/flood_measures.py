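"""Flood raster + census geography -> area flooded and population affected.

A 250 m categorical flood raster is summarized over a county: the fraction
of its pixels flagged as unusual flood (relative to all overlapping pixels,
clouds included) times the county area gives "Total Area Flooded"; every
census block touched by a flooded pixel contributes its whole population to
"Total Population Affected by Flooding".
"""

import numpy as np

import envmeasures as em
from envmeasures.rasters import CLASS_CODES

# one county of 25 km x 25 km, 2 tracts x 2 blocks, in planar meters
counties, tracts, blocks = em.generate_geography(em.GeographySpec(
    n_counties_x=1, n_counties_y=1, tracts_per_county=2, blocks_per_tract=2,
    county_width=25_000.0, county_height=25_000.0, coord_units="meters",
    seed=7,
))

# 100x100 raster covering the county exactly; flood a 40-pixel patch
classes = np.zeros((100, 100), dtype=np.uint8)
classes[:4, :10] = CLASS_CODES["unusual"]
raster = em.FloodRaster(classes=classes, origin_x=0.0, origin_y=25_000.0,
                        pixel_size=250.0, observation_date="2023-06-01")

county = counties[0]
prop = em.flooded_proportion(raster, county, "unusual")
area = em.total_area_flooded(raster, county, "unusual")
print(f"county area             : {county.area / 1e6:.1f} km2")
print(f"flooded pixel proportion: {prop:.4f}  (40 of 10,000 pixels)")
print(f"total area flooded      : {area:.2f} km2")

for m in em.population_affected(raster, blocks, counties + tracts, "unusual"):
    print(f"{m.level:7s} {m.jurisdiction_id:10s} "
          f"area {m.area_flooded_km2:6.2f} km2   "
          f"population affected {m.population_affected}")
print("  blocks touched anywhere by a flooded pixel count with their whole")
print("  population; tract totals sum exactly to their county")
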