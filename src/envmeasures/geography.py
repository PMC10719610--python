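"""Jurisdiction polygons and populated census blocks.

Counties, tracts and blocks are nested planar polygons: every block lies in
exactly one tract, every tract in exactly one county, and populations
aggregate upward by containment. Geographies are exchanged as GeoJSON
FeatureCollections with properties ``id``, ``parent_id``, ``level``,
``area``, ``utc_offset`` and, for blocks, ``population``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = ["Jurisdiction", "CensusBlock", "write_geojson", "read_geojson"]


@dataclass
class Jurisdiction:
    """A county or tract polygon.

    ``utc_offset`` is a fixed integer hour shift (no daylight saving) used to
    convert UTC series to the jurisdiction's local clock.
    """

    id: str
    level: str  # "county" | "tract"
    geometry: BaseGeometry
    utc_offset: int = 0
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.level not in ("county", "tract"):
            raise ValueError(f"level must be county or tract, got {self.level!r}")
        if not self.geometry.is_valid or self.geometry.area <= 0:
            raise ValueError(f"jurisdiction {self.id}: invalid or zero-area geometry")
        if self.utc_offset != int(self.utc_offset):
            raise ValueError("utc_offset must be an integer number of hours")
        self.utc_offset = int(self.utc_offset)

    @property
    def area(self) -> float:
        """Planar polygon area, in the square of the coordinate unit."""
        return self.geometry.area

    @property
    def centroid_lon(self) -> float:
        return self.geometry.centroid.x


@dataclass
class CensusBlock:
    """Smallest census unit; carries population and nests in tract and county."""

    id: str
    geometry: BaseGeometry
    population: int
    tract_id: str
    county_id: str

    def __post_init__(self) -> None:
        if self.population < 0 or self.population != int(self.population):
            raise ValueError(f"block {self.id}: population must be a non-negative integer")
        self.population = int(self.population)


def write_geojson(units, path) -> None:
    """Write jurisdictions or blocks as a GeoJSON FeatureCollection."""
    features = []
    for u in units:
        if isinstance(u, CensusBlock):
            props = {
                "id": u.id,
                "level": "block",
                "parent_id": u.tract_id,
                "county_id": u.county_id,
                "area": u.geometry.area,
                "population": u.population,
            }
        else:
            props = {
                "id": u.id,
                "level": u.level,
                "parent_id": u.parent_id,
                "area": u.area,
                "utc_offset": u.utc_offset,
            }
        features.append(
            {"type": "Feature", "geometry": mapping(u.geometry), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path):
    """Read a FeatureCollection back into Jurisdiction / CensusBlock objects."""
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        if props["level"] == "block":
            out.append(
                CensusBlock(
                    id=props["id"],
                    geometry=geom,
                    population=props["population"],
                    tract_id=props["parent_id"],
                    county_id=props["county_id"],
                )
            )
        else:
            out.append(
                Jurisdiction(
                    id=props["id"],
                    level=props["level"],
                    geometry=geom,
                    utc_offset=props.get("utc_offset", 0),
                    parent_id=props.get("parent_id"),
                )
            )
    return out
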