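"""Flood exposure measures: total area flooded and population affected.

Two jurisdiction-level measures are derived from a categorical flood
raster, separately for the recurring and unusual flood classes:

* **Total area flooded** — the proportion of raster pixels of the flood
  class intersecting the jurisdiction, relative to *all* pixels (any class,
  including cloud/no-data) intersecting it, multiplied by the jurisdiction's
  area. Keeping occluded pixels in the denominator means cloud cover biases
  the measure low rather than silently renormalizing; a clear-sky
  denominator is available behind ``denominator="clear_sky"``.
* **Total population affected** — the sum of the populations of every
  census block touched anywhere by a flood-class pixel, aggregated to the
  block's tract and county.

Permanent/known water is never counted as flood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import box
from shapely.prepared import prep

from .geography import CensusBlock, Jurisdiction
from .rasters import CLASS_CODES, FLOOD_CLASSES, FloodRaster

__all__ = [
    "FloodMeasure",
    "flooded_proportion",
    "total_area_flooded",
    "affected_blocks",
    "population_affected",
]

logger = logging.getLogger(__name__)

M2_PER_KM2 = 1e6


@dataclass
class FloodMeasure:
    """One jurisdiction-date-class record."""

    jurisdiction_id: str
    level: str
    observation_date: str
    flood_class: str
    area_flooded_km2: float
    population_affected: int


def _check_class(flood_class: str) -> int:
    if flood_class not in FLOOD_CLASSES:
        raise ValueError(
            f"flood_class must be one of {FLOOD_CLASSES}, got {flood_class!r}"
        )
    return CLASS_CODES[flood_class]


def _intersecting_pixels(raster: FloodRaster, geometry, mode: str = "area"):
    """Boolean mask of pixels whose footprint intersects the geometry.

    ``mode="area"``: positive-area overlap required (a pixel merely touching
    the boundary does not count). ``mode="touch"``: any intersection counts,
    including a shared edge or corner. ``mode="center"``: pixel-center
    containment (fast approximation).
    """
    n_rows, n_cols = raster.shape
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    minx, miny, maxx, maxy = geometry.bounds
    prepared = prep(geometry)
    for r in range(n_rows):
        px_miny = raster.origin_y - (r + 1) * raster.pixel_size
        px_maxy = raster.origin_y - r * raster.pixel_size
        if px_maxy < miny or px_miny > maxy:
            continue
        for c in range(n_cols):
            b = box(*raster.pixel_bounds(r, c))
            if mode == "center":
                mask[r, c] = prepared.contains(b.centroid)
            elif mode == "touch":
                mask[r, c] = prepared.intersects(b)
            else:
                mask[r, c] = prepared.intersects(b) and b.intersection(geometry).area > 0
    return mask


def flooded_proportion(
    raster: FloodRaster,
    jurisdiction: Jurisdiction,
    flood_class: str,
    denominator: str = "all",
    pixel_rule: str = "area",
) -> float:
    """Proportion of the jurisdiction's raster overlap carrying the class.

    Numerator: pixels of ``flood_class`` intersecting the polygon.
    Denominator: all intersecting pixels (``denominator="all"``, the
    default) or only cloud-free ones (``"clear_sky"``). NaN when the raster
    does not overlap the jurisdiction at all.
    """
    code = _check_class(flood_class)
    mask = _intersecting_pixels(raster, jurisdiction.geometry, mode=pixel_rule)
    total = int(mask.sum())
    if total == 0:
        logger.warning("jurisdiction %s: no raster overlap", jurisdiction.id)
        return float("nan")
    if denominator == "clear_sky":
        denom = int((mask & (raster.classes != CLASS_CODES["cloud"])).sum())
        if denom == 0:
            return float("nan")
    elif denominator == "all":
        denom = total
    else:
        raise ValueError(f"unknown denominator policy {denominator!r}")
    num = int((mask & (raster.classes == code)).sum())
    return num / denom


def total_area_flooded(
    raster: FloodRaster,
    jurisdiction: Jurisdiction,
    flood_class: str,
    denominator: str = "all",
    pixel_rule: str = "area",
) -> float:
    """Flooded proportion x jurisdiction area, in km^2 (area in m^2)."""
    p = flooded_proportion(
        raster, jurisdiction, flood_class,
        denominator=denominator, pixel_rule=pixel_rule,
    )
    return p * jurisdiction.area / M2_PER_KM2


def affected_blocks(
    raster: FloodRaster,
    blocks: list[CensusBlock],
    flood_class: str,
    pixel_rule: str = "touch",
) -> set[str]:
    """Ids of blocks touched anywhere by a pixel of the flood class.

    Any overlap counts, including a pixel straddling a shared block edge
    (which then affects both blocks).
    """
    code = _check_class(flood_class)
    flood_rows, flood_cols = np.nonzero(raster.classes == code)
    if flood_rows.size == 0:
        return set()
    footprints = [box(*raster.pixel_bounds(r, c)) for r, c in zip(flood_rows, flood_cols)]
    hit: set[str] = set()
    for blk in blocks:
        prepared = prep(blk.geometry)
        for fp in footprints:
            if pixel_rule == "center":
                if prepared.contains(fp.centroid):
                    hit.add(blk.id)
                    break
            elif prepared.intersects(fp):
                hit.add(blk.id)
                break
    return hit


def population_affected(
    raster: FloodRaster,
    blocks: list[CensusBlock],
    jurisdictions: list[Jurisdiction],
    flood_class: str,
    denominator: str = "all",
    pixel_rule: str = "touch",
) -> list[FloodMeasure]:
    """Per-jurisdiction flood measures for one class.

    Population affected is the sum over the jurisdiction's affected blocks;
    area flooded comes from :func:`total_area_flooded`. Blocks whose parent
    ids are not among the jurisdictions raise ``ValueError``.
    """
    known = {j.id for j in jurisdictions}
    for blk in blocks:
        parent = {"county": blk.county_id, "tract": blk.tract_id}
        for level, pid in parent.items():
            if any(j.level == level for j in jurisdictions) and pid not in known:
                raise ValueError(f"block {blk.id}: unknown {level} {pid!r}")

    hit = affected_blocks(raster, blocks, flood_class, pixel_rule=pixel_rule)
    out: list[FloodMeasure] = []
    for j in jurisdictions:
        if j.level == "county":
            pop = sum(b.population for b in blocks if b.county_id == j.id and b.id in hit)
        else:
            pop = sum(b.population for b in blocks if b.tract_id == j.id and b.id in hit)
        area = total_area_flooded(
            raster, j, flood_class, denominator=denominator, pixel_rule="area"
        )
        out.append(
            FloodMeasure(
                jurisdiction_id=j.id,
                level=j.level,
                observation_date=raster.observation_date,
                flood_class=flood_class,
                area_flooded_km2=area,
                population_affected=int(pop),
            )
        )
    return out
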