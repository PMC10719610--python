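"""Synthetic input generators: gridded fields, flood rasters, geographies.

Every downstream stage of the pipelines is testable offline because this
module emulates the three input families end to end:

* hourly gridded pollutant/temperature fields (diurnal sinusoid + Gaussian
  noise, clamped at zero) standing in for ~25 km forecast and ~50 km
  reanalysis products;
* single-date categorical flood rasters with i.i.d. per-pixel class draws,
  including cloud occlusion, standing in for ~250 m surface-water tiles;
* nested county → tract → block geographies that tile a planar rectangle
  exactly, blocks carrying integer populations.

All generators are deterministic given their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geography import CensusBlock, Jurisdiction
from .grids import GriddedField
from .rasters import CLASS_CODES, FloodRaster

__all__ = [
    "FieldSpec",
    "FloodSpec",
    "GeographySpec",
    "generate_pollutant_field",
    "generate_fields",
    "generate_flood_raster",
    "generate_geography",
]


@dataclass
class FieldSpec:
    """Recipe for one batch of co-gridded hourly fields.

    Cell values follow ``max(0, baseline + amplitude*sin(2*pi*hour/24) +
    N(0, noise_sd))`` independently per cell-hour. ``variables`` maps each
    variable name to its units; ``baseline``/``amplitude``/``noise_sd`` give
    per-variable values (missing keys default to 0 for amplitude/noise).
    """

    n_lon: int
    n_lat: int
    cell_size_deg: float
    origin_lon: float
    origin_lat: float
    n_hours: int
    variables: dict[str, str]  # name -> units
    baseline: dict[str, float]
    amplitude: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    start_time: str = "2023-06-01T00:00"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lon, self.n_lat, self.n_hours) < 1:
            raise ValueError("grid dimensions and n_hours must be >= 1")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be >= 0")
        for name in self.variables:
            if name not in self.baseline:
                raise ValueError(f"no baseline for variable {name!r}")


def generate_fields(spec: FieldSpec) -> dict[str, GriddedField]:
    """Generate one :class:`GriddedField` per variable in the spec.

    Deterministic given ``spec.seed``; each variable draws from its own
    seed-derived stream so adding a variable does not perturb the others.
    """
    lons = spec.origin_lon + spec.cell_size_deg * (np.arange(spec.n_lon) + 0.5)
    lats = spec.origin_lat + spec.cell_size_deg * (np.arange(spec.n_lat) + 0.5)
    timestamps = pd.date_range(spec.start_time, periods=spec.n_hours, freq="h")
    hours = timestamps.hour.to_numpy()
    diurnal = np.sin(2 * np.pi * hours / 24.0)[:, None, None]

    out: dict[str, GriddedField] = {}
    for i, (name, units) in enumerate(sorted(spec.variables.items())):
        rng = np.random.default_rng([spec.seed, i])
        base = spec.baseline[name]
        amp = spec.amplitude.get(name, 0.0)
        sd = spec.noise_sd.get(name, 0.0)
        shape = (spec.n_hours, spec.n_lat, spec.n_lon)
        noise = rng.normal(0.0, sd, size=shape) if sd > 0 else np.zeros(shape)
        vals = base + amp * diurnal + noise
        if units != "K":
            vals = np.maximum(vals, 0.0)
        out[name] = GriddedField(
            variable=name, values=vals, units=units, timestamps=timestamps, lons=lons, lats=lats
        )
    return out


def generate_pollutant_field(spec: FieldSpec, variable: str) -> GriddedField:
    """Generate a single variable from the spec (convenience wrapper)."""
    fields = generate_fields(spec)
    if variable not in fields:
        raise ValueError(f"variable {variable!r} not in spec")
    return fields[variable]


@dataclass
class FloodSpec:
    """Recipe for a categorical flood raster with i.i.d. per-pixel classes."""

    n_cols: int
    n_rows: int
    pixel_size: float = 250.0
    recurring_fraction: float = 0.0
    unusual_fraction: float = 0.0
    permanent_fraction: float = 0.0
    cloud_fraction: float = 0.0
    origin_x: float = 0.0
    origin_y: float | None = None  # default: top-left at n_rows * pixel_size
    observation_date: str = "2023-06-01"
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.recurring_fraction,
            self.unusual_fraction,
            self.permanent_fraction,
            self.cloud_fraction,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.n_cols, self.n_rows) < 1:
            raise ValueError("raster dimensions must be >= 1")
        if self.origin_y is None:
            self.origin_y = self.n_rows * self.pixel_size


def generate_flood_raster(spec: FloodSpec) -> FloodRaster:
    """Draw one class per pixel; realized counts are stored in metadata.

    The metadata counts are the ground truth tests compare against a
    re-scan of the raster.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.random((spec.n_rows, spec.n_cols))
    classes = np.full((spec.n_rows, spec.n_cols), CLASS_CODES["clear"], dtype=np.uint8)
    # cumulative thresholds partition [0, 1): recurring | unusual | permanent | cloud | clear
    edges = np.cumsum(
        [
            spec.recurring_fraction,
            spec.unusual_fraction,
            spec.permanent_fraction,
            spec.cloud_fraction,
        ]
    )
    classes[u < edges[0]] = CLASS_CODES["recurring"]
    classes[(u >= edges[0]) & (u < edges[1])] = CLASS_CODES["unusual"]
    classes[(u >= edges[1]) & (u < edges[2])] = CLASS_CODES["permanent"]
    classes[(u >= edges[2]) & (u < edges[3])] = CLASS_CODES["cloud"]

    raster = FloodRaster(
        classes=classes,
        origin_x=spec.origin_x,
        origin_y=spec.origin_y,
        pixel_size=spec.pixel_size,
        observation_date=spec.observation_date,
    )
    raster.metadata["class_counts"] = raster.class_counts()
    return raster


@dataclass
class GeographySpec:
    """Recipe for a nested county/tract/block geography.

    Counties tile an ``n_counties_x`` x ``n_counties_y`` rectangle of
    ``county_width`` x ``county_height`` cells; each county is split into
    ``tracts_per_county`` vertical strips, each tract into
    ``blocks_per_tract`` horizontal slabs, so containment and area sums are
    exact. Block populations are drawn uniformly on
    ``[population_low, population_high]``.

    ``coord_units`` selects the frame: ``"degrees"`` (air-quality path; UTC
    offset = round(centroid longitude / 15)) or ``"meters"`` (flood path;
    UTC offset 0).
    """

    n_counties_x: int
    n_counties_y: int
    tracts_per_county: int
    blocks_per_tract: int
    population_low: int = 100
    population_high: int = 5000
    origin_x: float = 0.0
    origin_y: float = 0.0
    county_width: float = 1.0
    county_height: float = 1.0
    coord_units: str = "degrees"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_counties_x,
            self.n_counties_y,
            self.tracts_per_county,
            self.blocks_per_tract,
        )
        if min(counts) < 1:
            raise ValueError("all counts must be >= 1")
        if self.population_low < 0 or self.population_high < self.population_low:
            raise ValueError("populations must satisfy 0 <= low <= high")
        if self.coord_units not in ("degrees", "meters"):
            raise ValueError("coord_units must be 'degrees' or 'meters'")


def _utc_offset(centroid_x: float, coord_units: str) -> int:
    if coord_units != "degrees":
        return 0
    # 15 degrees of longitude per hour; clamp to real-world offset range
    return int(np.clip(round(centroid_x / 15.0), -12, 14))


def generate_geography(
    spec: GeographySpec,
) -> tuple[list[Jurisdiction], list[Jurisdiction], list[CensusBlock]]:
    """Generate nested (counties, tracts, blocks).

    Identifiers are FIPS-like strings: county ``C<ix><iy>``, tract
    ``<county>T<k>``, block ``<tract>B<k>``.
    """
    rng = np.random.default_rng(spec.seed)
    counties: list[Jurisdiction] = []
    tracts: list[Jurisdiction] = []
    blocks: list[CensusBlock] = []

    for iy in range(spec.n_counties_y):
        for ix in range(spec.n_counties_x):
            cx0 = spec.origin_x + ix * spec.county_width
            cy0 = spec.origin_y + iy * spec.county_height
            cgeom = box(cx0, cy0, cx0 + spec.county_width, cy0 + spec.county_height)
            cid = f"C{ix:02d}{iy:02d}"
            counties.append(
                Jurisdiction(
                    id=cid,
                    level="county",
                    geometry=cgeom,
                    utc_offset=_utc_offset(cgeom.centroid.x, spec.coord_units),
                )
            )
            tract_w = spec.county_width / spec.tracts_per_county
            for it in range(spec.tracts_per_county):
                tx0 = cx0 + it * tract_w
                tgeom = box(tx0, cy0, tx0 + tract_w, cy0 + spec.county_height)
                tid = f"{cid}T{it:02d}"
                tracts.append(
                    Jurisdiction(
                        id=tid,
                        level="tract",
                        geometry=tgeom,
                        utc_offset=_utc_offset(tgeom.centroid.x, spec.coord_units),
                        parent_id=cid,
                    )
                )
                block_h = spec.county_height / spec.blocks_per_tract
                for ib in range(spec.blocks_per_tract):
                    by0 = cy0 + ib * block_h
                    bgeom = box(tx0, by0, tx0 + tract_w, by0 + block_h)
                    pop = int(rng.integers(spec.population_low, spec.population_high + 1))
                    blocks.append(
                        CensusBlock(
                            id=f"{tid}B{ib:02d}",
                            geometry=bgeom,
                            population=pop,
                            tract_id=tid,
                            county_id=cid,
                        )
                    )
    return counties, tracts, blocks
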