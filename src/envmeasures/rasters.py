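"""Categorical flood rasters with a north-up geotransform.

The raster emulates a daily MODIS-style surface-water classification at
~250 m: each pixel carries exactly one class code. GeoTIFF I/O is handled by
tifffile, writing the standard GeoTIFF ``ModelPixelScale`` and
``ModelTiepoint`` tags plus a JSON ``ImageDescription`` holding the
observation date and realized class counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "FloodRaster",
    "CLASS_CODES",
    "CLASS_NAMES",
    "FLOOD_CLASSES",
    "write_geotiff",
    "read_geotiff",
]

# Class codes, fixed by the interchange contract.
CLASS_CODES = {
    "clear": 0,
    "permanent": 1,
    "recurring": 2,
    "unusual": 3,
    "cloud": 255,  # cloud / no-data
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}
#: classes that count as flood (permanent/known water never does)
FLOOD_CLASSES = ("recurring", "unusual")

NODATA = CLASS_CODES["cloud"]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


@dataclass
class FloodRaster:
    """Single-date categorical raster.

    ``origin_x``/``origin_y`` locate the *top-left* corner of pixel (0, 0);
    rows advance southward (north-up raster). Coordinates are planar meters
    in synthetic mode.
    """

    classes: np.ndarray  # (n_rows, n_cols) uint8
    origin_x: float
    origin_y: float
    pixel_size: float
    observation_date: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.ndim != 2:
            raise ValueError("classes must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        known = set(CLASS_NAMES)
        found = set(np.unique(self.classes).tolist())
        if not found <= known:
            raise ValueError(f"unknown class codes {sorted(found - known)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the raster footprint."""
        n_rows, n_cols = self.classes.shape
        return (
            self.origin_x,
            self.origin_y - n_rows * self.pixel_size,
            self.origin_x + n_cols * self.pixel_size,
            self.origin_y,
        )

    def pixel_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """Footprint (min_x, min_y, max_x, max_y) of one pixel."""
        x0 = self.origin_x + col * self.pixel_size
        y1 = self.origin_y - row * self.pixel_size
        return (x0, y1 - self.pixel_size, x0 + self.pixel_size, y1)

    def class_counts(self) -> dict[str, int]:
        """Recount pixels per class by scanning the array."""
        counts = {}
        for name, code in CLASS_CODES.items():
            counts[name] = int(np.count_nonzero(self.classes == code))
        return counts


def write_geotiff(raster: FloodRaster, path) -> None:
    description = json.dumps(
        {"observation_date": raster.observation_date, "metadata": raster.metadata}
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (raster.pixel_size, raster.pixel_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, raster.origin_x, raster.origin_y, 0.0)),
    ]
    tifffile.imwrite(path, raster.classes, description=description, extratags=extratags)


def read_geotiff(path) -> FloodRaster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        classes = page.asarray()
        scale = page.tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = page.tags[_TAG_MODEL_TIEPOINT].value
        desc = page.tags.get("ImageDescription")
        info = json.loads(desc.value) if desc is not None else {}
    return FloodRaster(
        classes=classes,
        origin_x=float(tiepoint[3]),
        origin_y=float(tiepoint[4]),
        pixel_size=float(scale[0]),
        observation_date=info.get("observation_date", ""),
        metadata=info.get("metadata", {}),
    )
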