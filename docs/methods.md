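# Methods

envmeasures converts gridded environmental-hazard data into the daily,
jurisdiction-level measures used by environmental public health
surveillance systems: pollutant daily statistics with Air Quality Index
(AQI) values and categories, and flood extent / population-affected
measures. This note records the models, the parameters that matter, and
the design choices made where more than one defensible convention exists.

## Air-quality measures

### Speciated PM2.5 reconstruction

Reanalysis aerosol products report surface concentrations of individual
constituents rather than total PM2.5. Total PM2.5 (µg m⁻³) is the
element-wise sum

    PM2.5 = DU + SS + OC + BC + (132.14 / 96.06) · SO4

where DU is dust, SS sea salt, OC organic carbon, BC black carbon and SO4
the sulfate ion. The factor 132.14/96.06 is the molar-mass ratio of
ammonium sulfate to sulfate ion: sulfate is assumed fully neutralized as
(NH₄)₂SO₄, so the ammonium mass must be counted. Constituents arriving in
kg m⁻³ are scaled by 10⁹ first. A cell-hour missing in any constituent is
missing in the sum; negative input concentrations (reanalysis artifacts)
are coerced to missing at ingest.

### SO2 unit conversion

SO2 mass concentration becomes a mixing ratio via the ideal gas law at the
co-gridded air temperature:

    SO2 [ppb] = T [K] · SO2 [kg m⁻³] · 8.314×10⁷ / (1.013 · 64.066)

with 64.066 g mol⁻¹ the molar mass of SO2, the gas constant expressed in
the cm³-based unit system that makes the expression come out in ppb, and
1.013 the standard surface pressure in bar. The conversion is linear in
both inputs and is applied element-wise per cell-hour.

### Local time and daily statistics

Hourly series are produced in UTC and shifted to each jurisdiction's local
clock by a fixed integer offset (no daylight saving); day boundaries for
all daily statistics are local midnight-to-midnight. In synthetic mode the
offset is round(centroid longitude / 15°) clamped to [−12, +14].

Per-pollutant daily statistics follow surveillance practice:

| pollutant | statistic(s) |
|---|---|
| PM2.5 | 24-h mean |
| SO2 | 24-h mean and 1-h daily maximum |
| NO2 | 1-h daily maximum |
| CO, O3 | daily maximum 8-h rolling mean |

Completeness rules (configurable; defaults mirror regulatory practice): a
daily statistic requires ≥ 18 of the date's 24 hours valid (75%), else it
is reported missing with its completeness fraction attached. The rolling
statistic considers the 24 windows starting at each local hour; a window
may read up to 7 hours into the next local day (a midnight-clipped variant
is available), is valid with ≥ 6 of its 8 hours, and its mean is taken
over the hours available — the divisor is the count of valid hours, the
convention used in regulatory 8-h ozone averaging. With a 0–23 ramp and
the next day entirely missing this yields 20.5 (the window starting at
hour 18, mean of 18..23): windows partially out of data remain valid as
long as six hours survive. Statistics are computed after re-indexing onto
the date's full hourly grid, so explicitly-missing and simply-absent hours
are equivalent.

### AQI

The AQI maps a daily statistic onto 0–500 by piecewise-linear
interpolation between published breakpoint rows, after truncating (never
rounding) the concentration to the pollutant's reporting precision
(PM2.5: 1 decimal in µg m⁻³; O3: 3 decimals in ppm; CO: 1 decimal in ppm;
SO2, NO2: integer ppb). The interpolated value is rounded half-up to an
integer. Concentrations above the highest breakpoint ("beyond the AQI")
receive the highest category (Hazardous), the scale maximum of 500, and a
flag. Breakpoint tables are versioned CSV fixtures; the shipped default is
the 2018 technical-document vintage (PM2.5 Good/Moderate boundary at
12.0/12.1 µg m⁻³), so later revisions can be added as new versions without
code changes.

Two conventions the table fixture pins down explicitly:

* **SO2.** Both SO2 statistics are emitted, but only the 1-h maximum feeds
  AQI (the index for SO2 is 1-h based); the 24-h mean is a concentration
  measure without an index. The 1-h value is looked up against the full
  0–1004 ppb table; the regulatory refinement that indexes values ≥ 305
  ppb on a 24-h average instead is deliberately simplified away.
* **O3.** The 8-h table covers 0–0.200 ppm; higher 8-h means are treated
  as beyond-scale rather than switching to a 1-h table.

Numerics: truncation is done in decimal string arithmetic (binary floats
would truncate 35.4 to 35.3), and the interpolation in `Decimal` so that
exact half-integer ties (e.g. CO 3.3 ppm → 37.5) round deterministically
half-up instead of falling on whichever side float rounding lands.

## Grid-to-jurisdiction transformation

A sparse weight matrix is built once per (grid, geography, method) and
cached as TSV. Two methods:

* `area_weighted` (default): weight ∝ area of cell ∩ polygon, normalized
  per jurisdiction. The defensible default when counties straddle coarse
  (25–50 km) cells.
* `centroid`: all weight on the cell containing the jurisdiction
  centroid — the natural comparison when jurisdictions are much smaller
  than one cell.

At each hour, cells missing their value are dropped and remaining weights
renormalized; if less than half the total weight is valid the hour is
missing (floor configurable). The weighted mean is computed as
`ref + Σw(v−ref)/Σw` with a per-hour reference value, which is
algebraically identical but keeps constant fields exact — a bare
product-sum leaves ~10⁻¹⁶ residue that concentration truncation can
amplify into a whole AQI step.

## Flood measures

The flood raster is categorical at ~250 m: clear / permanent water /
recurring flood / unusual flood / cloud-no-data. Tiles sharing a pixel
grid are mosaicked (overlaps must agree exactly) and cropped to the
jurisdictions' bounding box, snapped outward to the pixel grid.

**Total area flooded** per jurisdiction and class: the number of
flood-class pixels whose footprint overlaps the polygon with positive
area, divided by the count of *all* overlapping pixels — cloud and no-data
included — times the jurisdiction's polygon area, reported in km².
Keeping occluded pixels in the denominator means cloud cover biases the
measure low rather than silently renormalizing; a `clear_sky` denominator
that excludes clouds is available by configuration. Permanent/known water
is never counted as flood. Recurring and unusual flooding are always
computed separately.

**Total population affected**: a census block is affected if a
flood-class pixel intersects it anywhere — boundary touch counts, and a
pixel straddling a shared edge affects both blocks; the block then
contributes its entire population (no areal apportionment — the rule is
binary). County and tract totals are sums over their affected blocks, so
the county value is exactly the sum over its tracts. A faster
pixel-center containment rule is available by configuration.

## Synthetic fixtures

The generator emulates the three input families so every stage is testable
offline, with all randomness seeded:

* **Fields**: per cell-hour, `max(0, baseline + amplitude·sin(2πh/24) +
  N(0, σ))` — a diurnal sinusoid plus Gaussian noise, clamped at zero.
  Each variable draws from its own seed-derived stream. This emulates the
  magnitude and daily cycle of hourly surface fields at 25–50 km; it does
  not emulate spatial correlation, synoptic weather, or chemistry, so
  passing tests demonstrate the *transforms* (aggregation, statistics,
  AQI), not atmospheric realism.
* **Flood rasters**: one class per pixel, i.i.d. draws with configured
  fractions for recurring/unusual/permanent/cloud; realized counts are
  stored in the raster metadata as ground truth. Spatial autocorrelation
  of real inundation is not emulated (nothing downstream depends on it).
* **Geography**: rectangular counties tile a plane; tracts split counties
  into vertical strips and blocks split tracts into horizontal slabs, so
  containment, areas and population sums are exact by construction. Block
  populations are uniform integers in [100, 5000] by default — a
  plausible block-size range, chosen once. The frame is selectable:
  degrees (air-quality path; UTC offsets derived from longitude) or
  planar meters (flood path; offsets 0). Real geographies would require
  an equal-area projection for the area step and actual time-zone
  polygons; both are documented extensions, not code paths.

## Pipelines

Offline-first: inputs are files on disk (NetCDF fields, GeoTIFF tiles,
GeoJSON geographies); the production system's scheduled remote queries are
represented by an unimplemented `RemoteFetcher` interface. The run date is
always an explicit config field, never the wall clock, so forecast-day
labelling (`hindcast-1`, `forecast+0` … `forecast+4`) is reproducible.
Outputs are long-format CSVs with `#` metadata headers plus a JSON run
manifest (inputs, package version, config hash, seed); identical config
and inputs reproduce outputs byte for byte. Excluded jurisdictions (zero
grid overlap) are logged with a reason and listed in the manifest.

Default problem sizes in the tests and the reproduction script — grids up
to ~20×20 cells, rasters up to 100×100 pixels, a handful of counties —
were chosen so brute-force oracles (per-cell and per-pixel loops) remain
exact and cheap to compare against.

## Known limitations

* Planar geometry throughout: no geodesic areas, no dateline handling,
  regular grids only.
* The model-derived measures are surveillance aids; they are not suitable
  for regulatory attainment determinations, and coarse cells can mask
  within-county gradients (many counties are smaller than one 50-km cell —
  the centroid method exists for exactly that comparison).
* Cloud occlusion biases flood measures low under the default
  denominator; the alternative biases them high under partial occlusion.
  Neither recovers what the cloud hides.
* Fixed integer UTC offsets ignore daylight saving and real time-zone
  boundaries.
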