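"""Grid-to-jurisdiction transformation and flood-tile mosaicking.

Gridded hourly fields become jurisdiction-level hourly series through a
sparse weight matrix built once per (grid, geography, method) and reused
across variables and runs. Two methods are provided: ``area_weighted``
(weight proportional to the cell ∩ polygon area — the defensible default
when jurisdictions straddle coarse cells) and ``centroid`` (all weight on
the cell containing the jurisdiction centroid — the right comparison when
jurisdictions are much smaller than a cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .aq import HourlySeries
from .geography import Jurisdiction
from .grids import GriddedField
from .rasters import NODATA, FloodRaster

__all__ = [
    "WeightMatrix",
    "build_weights",
    "aggregate_to_jurisdictions",
    "mosaic_and_clip",
]

logger = logging.getLogger(__name__)


@dataclass
class WeightMatrix:
    """Sparse (jurisdiction, cell) weights; per-jurisdiction weights sum to 1.

    ``table`` has columns jurisdiction_id, cell_row, cell_col, weight.
    Jurisdictions with zero grid overlap are recorded in ``excluded`` and
    absent from the table.
    """

    table: pd.DataFrame
    grid_signature: str
    method: str
    excluded: list[str]

    def for_jurisdiction(self, jid: str) -> pd.DataFrame:
        return self.table[self.table["jurisdiction_id"] == jid]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# grid_signature: {self.grid_signature}\n")
            fh.write(f"# method: {self.method}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path) -> "WeightMatrix":
        with open(path) as fh:
            sig = fh.readline().split(":", 1)[1].strip()
            method = fh.readline().split(":", 1)[1].strip()
            table = pd.read_csv(fh, sep="\t")
        return cls(table=table, grid_signature=sig, method=method, excluded=[])


def _cell_boxes(field: GriddedField):
    half = field.cell_size / 2.0
    boxes = []
    for r, lat in enumerate(field.lats):
        for c, lon in enumerate(field.lons):
            boxes.append((r, c, box(lon - half, lat - half, lon + half, lat + half)))
    return boxes


def build_weights(
    field: GriddedField,
    jurisdictions: list[Jurisdiction],
    method: str = "area_weighted",
) -> WeightMatrix:
    """Build normalized grid-cell weights for each jurisdiction.

    ``area_weighted``: weight ∝ area(cell ∩ polygon); ``centroid``: weight 1
    on the cell containing the jurisdiction's centroid. Jurisdictions with
    no overlap at all are excluded with a logged warning.
    """
    if method not in ("area_weighted", "centroid"):
        raise ValueError(f"unknown method {method!r}")
    cells = _cell_boxes(field)
    records = []
    excluded = []
    for j in jurisdictions:
        if method == "centroid":
            cen = j.geometry.centroid
            hit = [(r, c) for r, c, b in cells if b.covers(cen)]
            if not hit:
                excluded.append(j.id)
                logger.warning("jurisdiction %s: centroid outside grid, excluded", j.id)
                continue
            records.append((j.id, hit[0][0], hit[0][1], 1.0))
        else:
            areas = [(r, c, b.intersection(j.geometry).area) for r, c, b in cells
                     if b.intersects(j.geometry)]
            total = sum(a for _, _, a in areas)
            if total <= 0:
                excluded.append(j.id)
                logger.warning("jurisdiction %s: zero grid overlap, excluded", j.id)
                continue
            for r, c, a in areas:
                if a > 0:
                    records.append((j.id, r, c, a / total))
    table = pd.DataFrame(records, columns=["jurisdiction_id", "cell_row", "cell_col", "weight"])
    return WeightMatrix(
        table=table,
        grid_signature=field.grid_signature(),
        method=method,
        excluded=excluded,
    )


def aggregate_to_jurisdictions(
    field: GriddedField,
    weights: WeightMatrix,
    min_valid_weight: float = 0.5,
) -> dict[str, HourlySeries]:
    """Weighted spatial mean per jurisdiction at each hour.

    Cells missing at an hour are dropped and the remaining weights
    renormalized; when the valid weight falls below ``min_valid_weight``
    (i.e. more than half the weight is missing), the hour is missing.
    """
    if weights.grid_signature != field.grid_signature():
        raise ValueError("weight matrix was built against a different grid")
    out: dict[str, HourlySeries] = {}
    for jid, grp in weights.table.groupby("jurisdiction_id", sort=True):
        rows = grp["cell_row"].to_numpy(dtype=int)
        cols = grp["cell_col"].to_numpy(dtype=int)
        w = grp["weight"].to_numpy()
        vals = field.values[:, rows, cols]  # (n_time, k)
        valid = np.isfinite(vals)
        wsum = np.where(valid, w, 0.0).sum(axis=1)
        # weighted mean as ref + sum(w*(v-ref))/sum(w): exact for constant
        # fields, where a bare product-sum would leave ~1e-16 residue that
        # downstream concentration truncation can amplify a whole AQI step
        any_valid = valid.any(axis=1)
        ref_idx = np.argmax(valid, axis=1)
        ref = np.where(any_valid, vals[np.arange(vals.shape[0]), ref_idx], 0.0)
        deltas = np.where(valid, (vals - ref[:, None]) * w, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            series_vals = np.where(
                wsum >= min_valid_weight, ref + deltas / wsum, np.nan
            )
        out[str(jid)] = HourlySeries(
            jurisdiction_id=str(jid),
            pollutant=field.variable,
            values=pd.Series(series_vals, index=field.timestamps),
            units=field.units,
        )
    return out


def _snap(value: float, origin: float, step: float, up: bool) -> int:
    """Index of the grid line at/beyond ``value`` measured from origin."""
    k = (value - origin) / step
    return int(np.ceil(k)) if up else int(np.floor(k))


def mosaic_and_clip(tiles: list[FloodRaster], extent) -> FloodRaster:
    """Mosaic aligned tiles and crop to the extent's bounding box.

    Tiles must share pixel size and grid alignment and agree wherever they
    overlap. Pixels of the output covered by no tile are no-data. The crop
    is snapped outward to the pixel grid so every pixel touching the extent
    survives.
    """
    if not tiles:
        raise ValueError("no tiles to mosaic")
    px = tiles[0].pixel_size
    ox, oy = tiles[0].origin_x, tiles[0].origin_y
    for t in tiles[1:]:
        if t.pixel_size != px:
            raise ValueError("tiles differ in pixel size")
        if (round((t.origin_x - ox) / px, 9) % 1 != 0
                or round((oy - t.origin_y) / px, 9) % 1 != 0):
            raise ValueError("tiles are not aligned to a common pixel grid")

    minx, miny, maxx, maxy = extent.bounds
    col0 = _snap(minx, ox, px, up=False)
    col1 = _snap(maxx, ox, px, up=True)
    row0 = _snap(oy - maxy, 0.0, px, up=False)
    row1 = _snap(oy - miny, 0.0, px, up=True)
    n_rows, n_cols = row1 - row0, col1 - col0
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("extent has zero pixel footprint")

    out = np.full((n_rows, n_cols), NODATA, dtype=np.uint8)
    filled = np.zeros((n_rows, n_cols), dtype=bool)
    any_tile = False
    for t in tiles:
        t_col0 = int(round((t.origin_x - ox) / px))
        t_row0 = int(round((oy - t.origin_y) / px))
        tr, tc = t.classes.shape
        # overlap of tile with the output window, in output indices
        r0 = max(row0, t_row0); r1 = min(row1, t_row0 + tr)
        c0 = max(col0, t_col0); c1 = min(col1, t_col0 + tc)
        if r0 >= r1 or c0 >= c1:
            continue
        any_tile = True
        sub = t.classes[r0 - t_row0 : r1 - t_row0, c0 - t_col0 : c1 - t_col0]
        view = out[r0 - row0 : r1 - row0, c0 - col0 : c1 - col0]
        fview = filled[r0 - row0 : r1 - row0, c0 - col0 : c1 - col0]
        conflict = fview & (view != sub)
        if conflict.any():
            raise ValueError("overlapping tiles disagree")
        view[...] = sub
        fview[...] = True
    if not any_tile:
        logger.warning("extent overlaps no tile; returning all no-data raster")

    return FloodRaster(
        classes=out,
        origin_x=ox + col0 * px,
        origin_y=oy - row0 * px,
        pixel_size=px,
        observation_date=tiles[0].observation_date,
    )
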