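"""End-to-end pipeline runs: fields/rasters on disk in, measure CSVs out.

The pipelines are offline-first: they consume NetCDF fields, GeoTIFF flood
tiles and GeoJSON geographies already on disk (the remote-query step of the
production system is represented by :class:`RemoteFetcher`, a documented
interface left unimplemented). Every run writes its measure CSV plus a JSON
run manifest (inputs, package version, config hash, seed, run date) so runs
are reproducible byte for byte.

Modes
-----
``aq_forecast``
    Hourly pollutant fields → daily statistics + AQI per jurisdiction, with
    each output day labelled relative to the configured run date: a 1-day
    hindcast and a 4-day forecast that includes the run date itself.
``aq_historical``
    Same computation, reanalysis style: speciated PM2.5 is reconstructed
    from constituents when no direct PM2.5 variable is present, and SO2
    arriving as kg m^-3 is converted to ppb with the co-gridded temperature.
``flood``
    Flood tiles → mosaic → clip → per-jurisdiction, per-class total area
    flooded and population affected, at county and tract level.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import box
from shapely.ops import unary_union

from . import __version__
from .aq import (
    STATISTICS_BY_POLLUTANT,
    compute_daily_statistics,
    convert_constituents_to_ug,
    reconstruct_pm25,
    so2_mass_to_ppb,
    utc_to_local,
    PM25_CONSTITUENTS,
)
from .aqi import compute_aqi, load_breakpoints
from .flood import population_affected
from .geography import CensusBlock, Jurisdiction, read_geojson
from .grids import read_fields_netcdf
from .rasters import FLOOD_CLASSES, read_geotiff
from .spatial import aggregate_to_jurisdictions, build_weights, mosaic_and_clip

__all__ = ["PipelineConfig", "run_aq_pipeline", "run_flood_pipeline", "RemoteFetcher"]

logger = logging.getLogger(__name__)

MEASURE_NAMES = {
    "flood": ["Total Area Flooded", "Total Population Affected by Flooding"],
}

AQ_COLUMNS = [
    "jurisdiction_id", "local_date", "day_label", "pollutant", "statistic",
    "value", "units", "completeness", "aqi", "category", "beyond_flag",
]
FLOOD_COLUMNS = [
    "jurisdiction_id", "level", "date", "flood_class",
    "area_flooded_km2", "population_affected",
]


class RemoteFetcher:
    """Interface for the remote-query step of the production system.

    The deployed pipeline pulls its inputs from remote data services on a
    schedule; this artifact consumes files on disk instead. Implementations
    would download the configured products for a run date and return local
    paths. Deliberately unimplemented here.
    """

    def fetch(self, run_date: str) -> list[str]:
        raise NotImplementedError("offline artifact: place input files on disk")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from a YAML file."""

    mode: str  # aq_forecast | aq_historical | flood
    out_dir: str
    fields_path: str | None = None
    raster_paths: list[str] = field(default_factory=list)
    geography_path: str | None = None
    variable_map: dict[str, str] = field(default_factory=dict)
    aggregation_method: str = "area_weighted"
    min_valid_hours: int = 18
    min_window_valid_hours: int = 6
    breakpoint_version: str = "2018"
    denominator: str = "all"
    pixel_rule: str = "touch"
    run_date: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("aq_forecast", "aq_historical", "flood"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode.startswith("aq"):
            if not self.fields_path:
                raise ValueError("aq modes require fields_path")
            if self.mode == "aq_forecast" and not self.run_date:
                raise ValueError("aq_forecast requires run_date")
        else:
            if not self.raster_paths:
                raise ValueError("flood mode requires raster_paths")
        if not self.geography_path:
            raise ValueError("geography_path is required")
        for p in [self.fields_path, self.geography_path, *self.raster_paths]:
            if p and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(config: PipelineConfig, outputs: list[str], notes: dict) -> str:
    manifest = {
        "package_version": __version__,
        "mode": config.mode,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "run_date": config.run_date,
        "inputs": sorted(
            Path(p).name
            for p in [config.fields_path, config.geography_path, *config.raster_paths]
            if p
        ),
        "outputs": sorted(Path(p).name for p in outputs),
        **notes,
    }
    path = str(Path(config.out_dir) / "run_manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def _write_csv(df: pd.DataFrame, path, header_lines: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def _day_label(local_date: str, run_date: str | None) -> str:
    if run_date is None:
        return ""
    offset = (pd.Timestamp(local_date) - pd.Timestamp(run_date)).days
    if offset == -1:
        return "hindcast-1"
    if 0 <= offset <= 4:
        return f"forecast+{offset}"
    return ""


def _prepare_aq_fields(fields: dict, config: PipelineConfig) -> tuple[dict, dict]:
    """Unit conversions + PM2.5 reconstruction; returns (fields, notes)."""
    notes: dict = {"pm25_source": None}
    fields = {name: f.mask_negative() for name, f in fields.items()}

    for name in PM25_CONSTITUENTS:
        if name in fields and fields[name].units == "kg m^-3":
            fields[name] = convert_constituents_to_ug(fields[name])

    if "PM25" in fields:
        notes["pm25_source"] = "direct"
    elif all(c in fields for c in PM25_CONSTITUENTS):
        fields["PM25"] = reconstruct_pm25(*(fields[c] for c in PM25_CONSTITUENTS))
        notes["pm25_source"] = "reconstructed"

    if "SO2" in fields and fields["SO2"].units == "kg m^-3":
        if "T" not in fields:
            raise ValueError("SO2 in kg m^-3 requires a temperature field 'T'")
        fields["SO2"] = so2_mass_to_ppb(fields["SO2"], fields["T"])
    return fields, notes


def run_aq_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Aggregate → localize → daily statistics → AQI → CSV + manifest."""
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    fields = read_fields_netcdf(config.fields_path, config.variable_map)
    fields, notes = _prepare_aq_fields(fields, config)

    pollutants = [p for p in sorted(STATISTICS_BY_POLLUTANT) if p in fields]
    missing = [p for p in ("PM25",) if p not in fields and notes["pm25_source"] is None]
    if not pollutants:
        raise ValueError(
            "no computable pollutant among input variables; "
            f"have {sorted(fields)}, missing e.g. {missing or sorted(STATISTICS_BY_POLLUTANT)}"
        )

    geos = read_geojson(config.geography_path)
    jurisdictions = [g for g in geos if isinstance(g, Jurisdiction)]
    if not jurisdictions:
        raise ValueError("geography file contains no jurisdictions")

    table = load_breakpoints(config.breakpoint_version)
    any_field = fields[pollutants[0]]
    weights = build_weights(any_field, jurisdictions, method=config.aggregation_method)
    offsets = {j.id: j.utc_offset for j in jurisdictions}

    rows = []
    for pol in pollutants:
        series_by_jur = aggregate_to_jurisdictions(fields[pol], weights)
        aqi_stat = table.statistic(pol) if pol in table.pollutants() else None
        for jid, series in series_by_jur.items():
            local = utc_to_local(series, offsets[jid])
            for stat in compute_daily_statistics(
                pol, local,
                min_valid_hours=config.min_valid_hours,
                min_window_valid_hours=config.min_window_valid_hours,
            ):
                aqi = cat = beyond = None
                if aqi_stat == stat.statistic and not stat.is_missing:
                    res = compute_aqi(stat, table)
                    aqi, cat, beyond = res.aqi_value, res.category, res.beyond_flag
                rows.append(
                    {
                        "jurisdiction_id": jid,
                        "local_date": stat.local_date,
                        "day_label": _day_label(
                            stat.local_date,
                            config.run_date if config.mode == "aq_forecast" else None,
                        ),
                        "pollutant": pol,
                        "statistic": stat.statistic,
                        "value": stat.value,
                        "units": stat.units,
                        "completeness": stat.completeness,
                        "aqi": aqi,
                        "category": cat,
                        "beyond_flag": beyond,
                    }
                )

    df = pd.DataFrame(rows, columns=AQ_COLUMNS).sort_values(
        ["pollutant", "jurisdiction_id", "local_date", "statistic"]
    ).reset_index(drop=True)
    df["aqi"] = df["aqi"].astype("Int64")
    out_csv = str(Path(config.out_dir) / "aq_measures.csv")
    _write_csv(
        df, out_csv,
        [
            f"mode: {config.mode}",
            "measures: daily pollutant statistics with AQI value and category",
            "units: per-row 'units' column; aqi dimensionless 0-500",
            f"pm25_source: {notes['pm25_source']}",
        ],
    )
    notes["excluded_jurisdictions"] = weights.excluded
    for jid in weights.excluded:
        logger.warning("excluded jurisdiction %s: no grid overlap", jid)
    _write_manifest(config, [out_csv], notes)
    return df


def run_flood_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Mosaic → clip → per-jurisdiction, per-class flood measures → CSV."""
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    tiles = [read_geotiff(p) for p in config.raster_paths]

    geos = read_geojson(config.geography_path)
    jurisdictions = [g for g in geos if isinstance(g, Jurisdiction)]
    blocks = [g for g in geos if isinstance(g, CensusBlock)]
    if not jurisdictions:
        raise ValueError("geography file contains no jurisdictions")

    extent = unary_union([j.geometry for j in jurisdictions])
    raster = mosaic_and_clip(tiles, box(*extent.bounds))

    rows = []
    for flood_class in FLOOD_CLASSES:
        for m in population_affected(
            raster, blocks, jurisdictions, flood_class,
            denominator=config.denominator, pixel_rule=config.pixel_rule,
        ):
            rows.append(
                {
                    "jurisdiction_id": m.jurisdiction_id,
                    "level": m.level,
                    "date": m.observation_date,
                    "flood_class": m.flood_class,
                    "area_flooded_km2": m.area_flooded_km2,
                    "population_affected": m.population_affected,
                }
            )

    df = pd.DataFrame(rows, columns=FLOOD_COLUMNS).sort_values(
        ["flood_class", "level", "jurisdiction_id"]
    ).reset_index(drop=True)
    out_csv = str(Path(config.out_dir) / "flood_measures.csv")
    _write_csv(
        df, out_csv,
        [
            "measures: " + "; ".join(MEASURE_NAMES["flood"]),
            "units: area_flooded_km2 in km^2; population_affected in persons",
            f"denominator: {config.denominator}",
        ],
    )
    _write_manifest(config, [out_csv], {"n_tiles": len(tiles)})
    return df
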