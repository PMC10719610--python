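# envmeasures

Jurisdiction-level daily environmental-hazard measures from gridded data:
pollutant daily statistics with Air Quality Index (AQI) categories, and
flood extent / population-affected estimates.

Public health surveillance systems track environmental hazards per
county and census tract, per day. Model and satellite products deliver
something very different — hourly pollutant fields on 25–50 km grids and
~250 m categorical flood rasters. envmeasures implements the measure
pipeline between the two:

* **Air quality** — reconstruct total PM2.5 from speciated aerosol
  constituents (`PM2.5 = DU + SS + OC + BC + (132.14/96.06)·SO4`),
  convert SO2 mass concentration to ppb
  (`T·SO2·8.314×10⁷/(1.013·64.066)`), aggregate grid cells to
  jurisdictions (area-weighted or centroid), shift to local time, compute
  the daily statistics (24-h mean, 1-h max, max 8-h rolling mean with 75%
  completeness rules) and map them to the 0–500 AQI and its six
  health-concern categories, including the beyond-scale rule.
* **Flooding** — mosaic and clip categorical flood tiles, then per
  jurisdiction and flood class (recurring vs unusual): total area flooded
  (flooded-pixel proportion × jurisdiction area) and total population
  affected (sum of populations of every census block touched by a flooded
  pixel).
* **Synthetic fixtures** — seeded generators for all three input families
  (hourly fields, flood rasters, nested county/tract/block geographies
  with populations), so the full pipeline runs and is tested entirely
  offline.

See `docs/methods.md` for the conventions and their rationale.

## Worked example

```sh
python examples/flood_measures.py
```

```
county area             : 625.0 km2
flooded pixel proportion: 0.0040  (40 of 10,000 pixels)
total area flooded      : 2.50 km2
county  C0000      area   2.50 km2   population affected 3163
tract   C0000T00   area   2.50 km2   population affected 3163
tract   C0000T01   area   0.00 km2   population affected 0
```

A 100×100 raster of 250 m pixels covers one 625 km² county; 40 pixels of
unusual flood give a proportion of 0.004, hence 2.5 km² of flooded area.
The flooded patch touches blocks totalling 3 163 residents in one tract;
tract populations sum exactly to the county. The other examples walk the
PM2.5/SO2 equations (`reconstruct_pm25.py`), an ozone day from hourly
series to AQI category (`daily_statistics_and_aqi.py`), and a full
two-pipeline run with forecast-day labels (`end_to_end_pipeline.py`).

A thin CLI wraps the same library: `envmeasures synth` (emit fixtures),
`envmeasures aq` / `envmeasures flood` (run a pipeline from a YAML
config), `envmeasures validate` (schema-check an output CSV).

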