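"""Gridded hourly fields on a regular lon/lat grid.

:class:`GriddedField` is the carrier for every hourly surface variable the
pipelines consume: speciated aerosol constituents, gas-phase pollutants and
air temperature. Values live in a ``(time, lat, lon)`` array with NaN marking
missing cells; timestamps are tz-naive UTC hours. NetCDF round-tripping goes
through xarray (CF-style dimensions ``time``/``lat``/``lon`` and a ``units``
attribute per variable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["GriddedField", "write_fields_netcdf", "read_fields_netcdf"]

#: units accepted on ingest
VALID_UNITS = {"kg m^-3", "ug m^-3", "ppb", "ppm", "K"}


class GridAlignmentError(ValueError):
    """Two fields do not share a grid and time axis."""


class UnitError(ValueError):
    """A field arrived with units other than the ones an operation expects."""


@dataclass
class GriddedField:
    """One variable's hourly values on a regular lon/lat grid.

    Parameters
    ----------
    variable
        Canonical variable name (e.g. ``"SO2"``, ``"DU"``, ``"T"``).
    values
        Array of shape ``(n_time, n_lat, n_lon)``; NaN means missing.
    units
        One of ``kg m^-3``, ``ug m^-3``, ``ppb``, ``ppm``, ``K``.
    timestamps
        Strictly increasing, hourly, tz-naive UTC.
    lons, lats
        Cell-centre coordinates in degrees, evenly spaced.
    """

    variable: str
    values: np.ndarray
    units: str
    timestamps: pd.DatetimeIndex
    lons: np.ndarray = field(repr=False, default=None)
    lats: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.units not in VALID_UNITS:
            raise UnitError(f"unknown units {self.units!r}")
        if self.values.ndim != 3:
            raise ValueError("values must be (time, lat, lon)")
        if self.values.shape != (len(self.timestamps), len(self.lats), len(self.lons)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with axes "
                f"({len(self.timestamps)}, {len(self.lats)}, {len(self.lons)})"
            )
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8)
            if not np.all(deltas == 3_600_000_000_000):
                raise ValueError("timestamps must be strictly increasing hourly")

    # -- geometry -----------------------------------------------------------

    @property
    def cell_size(self) -> float:
        """Grid spacing in degrees (regular grid)."""
        if len(self.lons) > 1:
            return float(self.lons[1] - self.lons[0])
        if len(self.lats) > 1:
            return float(self.lats[1] - self.lats[0])
        raise ValueError("cell size undefined for a 1x1 grid without spacing")

    def grid_signature(self) -> str:
        """Stable key identifying the grid (used for weight caching)."""
        return (
            f"lon{self.lons[0]:.6f}+{len(self.lons)}"
            f"_lat{self.lats[0]:.6f}+{len(self.lats)}"
            f"_d{self.cell_size:.6f}"
        )

    # -- hygiene ------------------------------------------------------------

    def mask_negative(self) -> "GriddedField":
        """Coerce physically impossible negative concentrations to missing.

        Temperature (K) is exempt; reanalysis concentration fields can carry
        small negative artifacts which must not leak into statistics.
        """
        if self.units == "K":
            return self
        vals = self.values.copy()
        vals[vals < 0] = np.nan
        return replace(self, values=vals)

    def check_aligned(self, other: "GriddedField") -> None:
        """Raise :class:`GridAlignmentError` unless grids and times match."""
        if (
            self.values.shape != other.values.shape
            or not np.array_equal(self.lons, other.lons)
            or not np.array_equal(self.lats, other.lats)
            or not self.timestamps.equals(other.timestamps)
        ):
            raise GridAlignmentError(
                f"{self.variable} and {other.variable} are not on the same grid/time axis"
            )

    # -- xarray / NetCDF ----------------------------------------------------

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": self.timestamps, "lat": self.lats, "lon": self.lons},
            name=self.variable,
            attrs={"units": self.units},
        )

    @classmethod
    def from_dataarray(cls, da: xr.DataArray, variable: str | None = None) -> "GriddedField":
        return cls(
            variable=variable or str(da.name),
            values=np.asarray(da.values, dtype=float),
            units=str(da.attrs["units"]),
            timestamps=pd.DatetimeIndex(da["time"].values),
            lons=np.asarray(da["lon"].values, dtype=float),
            lats=np.asarray(da["lat"].values, dtype=float),
        )


def write_fields_netcdf(fields: dict[str, GriddedField], path) -> None:
    """Write a set of co-gridded fields to one CF-style NetCDF file."""
    ds = xr.Dataset({name: f.to_dataarray() for name, f in fields.items()})
    ds.to_netcdf(path, engine="scipy")


def read_fields_netcdf(path, variable_map: dict[str, str] | None = None) -> dict[str, GriddedField]:
    """Read all variables from a NetCDF file into :class:`GriddedField` objects.

    ``variable_map`` renames file variables to canonical names
    (``{file_name: canonical_name}``).
    """
    variable_map = variable_map or {}
    with xr.open_dataset(path, engine="scipy") as ds:
        out: dict[str, GriddedField] = {}
        for name in ds.data_vars:
            canon = variable_map.get(str(name), str(name))
            out[canon] = GriddedField.from_dataarray(ds[name].load(), variable=canon)
    return out
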