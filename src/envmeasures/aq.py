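"""Pollutant concentration computations and daily statistics.

Implements the transformations that turn hourly reanalysis/forecast fields
into the daily per-jurisdiction concentration statistics used for public
health surveillance:

* speciated PM2.5 reconstruction — total PM2.5 is the sum of the dust, sea
  salt, organic carbon and black carbon constituents plus sulfate scaled by
  the ammonium-sulfate/sulfate-ion molar-mass ratio 132.14/96.06 (sulfate is
  assumed fully neutralized as ammonium sulfate);
* SO2 mass-to-mixing-ratio conversion, ppb = T[K] * SO2[kg m^-3] * 8.314e7
  / (1.013 * 64.066);
* UTC → local-time shift by a fixed integer offset per jurisdiction;
* daily statistics per pollutant: 24-h mean (PM2.5, SO2), 1-h daily max
  (SO2, NO2), and the daily maximum 8-h rolling mean (CO, O3), with a 75%
  completeness rule (>= 18 of 24 valid hours per day, >= 6 of 8 per rolling
  window; rolling windows start at each local hour and may read up to 7
  hours into the next local day).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grids import GriddedField, UnitError

__all__ = [
    "SULFATE_TO_AMMONIUM_SULFATE",
    "reconstruct_pm25",
    "convert_constituents_to_ug",
    "so2_mass_to_ppb",
    "HourlySeries",
    "utc_to_local",
    "DailyStatistic",
    "daily_mean_24h",
    "daily_max_1h",
    "max_rolling_8h",
    "compute_daily_statistics",
    "STATISTICS_BY_POLLUTANT",
]

# molar masses, g/mol
MOLAR_MASS_AMMONIUM_SULFATE = 132.14
MOLAR_MASS_SULFATE_ION = 96.06
MOLAR_MASS_SO2 = 64.066
# universal gas constant in the cm^3-based unit system the conversion uses
GAS_CONSTANT_FACTOR = 8.314e7
PRESSURE_FACTOR = 1.013

SULFATE_TO_AMMONIUM_SULFATE = MOLAR_MASS_AMMONIUM_SULFATE / MOLAR_MASS_SULFATE_ION

PM25_CONSTITUENTS = ("DU", "SS", "OC", "BC", "SO4")


def reconstruct_pm25(
    du: GriddedField,
    ss: GriddedField,
    oc: GriddedField,
    bc: GriddedField,
    so4: GriddedField,
) -> GriddedField:
    """Total PM2.5 from aerosol constituents, element-wise.

    PM2.5 = DU + SS + OC + BC + (132.14/96.06) * SO4, all in ug m^-3.
    A cell-hour missing in any constituent is missing in the result.
    """
    fields = (du, ss, oc, bc, so4)
    for f in fields:
        if f.units != "ug m^-3":
            raise UnitError(f"{f.variable}: constituents must be in ug m^-3, got {f.units}")
        du.check_aligned(f)
    values = (
        du.values + ss.values + oc.values + bc.values
        + SULFATE_TO_AMMONIUM_SULFATE * so4.values
    )
    return replace(du, variable="PM25", values=values)


def convert_constituents_to_ug(field: GriddedField) -> GriddedField:
    """kg m^-3 → ug m^-3 (x 1e9)."""
    if field.units != "kg m^-3":
        raise UnitError(f"{field.variable}: expected kg m^-3, got {field.units}")
    return replace(field, values=field.values * 1e9, units="ug m^-3")


def so2_mass_to_ppb(so2: GriddedField, temperature: GriddedField) -> GriddedField:
    """Convert SO2 mass concentration to a ppb mixing ratio.

    ppb = T[K] * SO2[kg m^-3] * 8.314e7 / (1.013 * 64.066), element-wise at
    each cell-hour, using the co-gridded air temperature.
    """
    if so2.units != "kg m^-3":
        raise UnitError(f"SO2 must be in kg m^-3, got {so2.units}")
    if temperature.units != "K":
        raise UnitError(f"temperature must be in K, got {temperature.units}")
    so2.check_aligned(temperature)
    values = (
        temperature.values * so2.values * GAS_CONSTANT_FACTOR
        / (PRESSURE_FACTOR * MOLAR_MASS_SO2)
    )
    return replace(so2, values=values, units="ppb")


@dataclass
class HourlySeries:
    """Hourly values for one jurisdiction and pollutant.

    ``values`` is indexed by hourly timestamps (UTC until
    :func:`utc_to_local` is applied); NaN marks missing hours explicitly.
    """

    jurisdiction_id: str
    pollutant: str
    values: pd.Series
    units: str
    timezone: str = "UTC"  # "UTC" or "local"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not isinstance(self.values.index, pd.DatetimeIndex):
            raise ValueError("values must be indexed by timestamps")


def utc_to_local(series: HourlySeries, utc_offset: int) -> HourlySeries:
    """Shift timestamps by a fixed integer hour offset; values unchanged.

    Daily statistics downstream use local midnight-to-midnight boundaries.
    """
    if utc_offset != int(utc_offset):
        raise ValueError("utc_offset must be an integer number of hours")
    shifted = series.values.copy()
    shifted.index = shifted.index + pd.Timedelta(hours=int(utc_offset))
    return replace(series, values=shifted, timezone="local")


@dataclass
class DailyStatistic:
    """One jurisdiction-date-pollutant statistic.

    ``value`` is NaN when the completeness rule suppresses the statistic;
    ``completeness`` is the fraction of the local date's 24 hours that were
    valid regardless.
    """

    jurisdiction_id: str
    local_date: str  # ISO date
    pollutant: str
    statistic: str  # mean_24h | max_1h | max_rolling_8h
    value: float
    completeness: float
    units: str

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.value)


def _day_values(series: HourlySeries, date, extra_hours: int = 0) -> pd.Series:
    """Reindex to the date's 24 (+extra) hourly stamps; absent hours → NaN.

    Reindexing makes statistics invariant to whether missing hours were
    stored explicitly or simply absent from the series.
    """
    start = pd.Timestamp(date)
    idx = pd.date_range(start, periods=24 + extra_hours, freq="h")
    return series.values.reindex(idx)


def _completeness(day: pd.Series) -> float:
    return float(day.iloc[:24].notna().sum()) / 24.0


def daily_mean_24h(
    series: HourlySeries, date, min_valid_hours: int = 18
) -> DailyStatistic:
    """Arithmetic mean of the valid hours in the local date."""
    day = _day_values(series, date)
    comp = _completeness(day)
    value = float(day.mean()) if day.notna().sum() >= min_valid_hours else np.nan
    return DailyStatistic(
        series.jurisdiction_id, str(pd.Timestamp(date).date()), series.pollutant,
        "mean_24h", value, comp, series.units,
    )


def daily_max_1h(
    series: HourlySeries, date, min_valid_hours: int = 18
) -> DailyStatistic:
    """Maximum of the valid hourly values in the local date."""
    day = _day_values(series, date)
    comp = _completeness(day)
    value = float(day.max()) if day.notna().sum() >= min_valid_hours else np.nan
    return DailyStatistic(
        series.jurisdiction_id, str(pd.Timestamp(date).date()), series.pollutant,
        "max_1h", value, comp, series.units,
    )


def max_rolling_8h(
    series: HourlySeries,
    date,
    min_valid_hours: int = 18,
    min_window_valid_hours: int = 6,
    clip_at_midnight: bool = False,
) -> DailyStatistic:
    """Daily maximum 8-hour rolling mean.

    The 24 candidate windows start at each local hour of the date; a window
    spills up to 7 hours into the next local day unless ``clip_at_midnight``.
    A window is valid with >= ``min_window_valid_hours`` of its 8 hours
    present, and its mean is taken over the available hours (the divisor is
    the number of valid hours). The daily statistic additionally requires
    >= ``min_valid_hours`` valid hours within the date itself.
    """
    extra = 0 if clip_at_midnight else 7
    day = _day_values(series, date, extra_hours=extra)
    comp = _completeness(day)
    if day.iloc[:24].notna().sum() < min_valid_hours:
        value = np.nan
    else:
        vals = day.to_numpy()
        best = -np.inf
        for start in range(24):
            window = vals[start : start + 8]
            valid = window[np.isfinite(window)]
            if valid.size >= min_window_valid_hours:
                best = max(best, float(valid.mean()))
        value = best if np.isfinite(best) else np.nan
    return DailyStatistic(
        series.jurisdiction_id, str(pd.Timestamp(date).date()), series.pollutant,
        "max_rolling_8h", value, comp, series.units,
    )


#: statistic dispatch per pollutant
STATISTICS_BY_POLLUTANT: dict[str, tuple[str, ...]] = {
    "PM25": ("mean_24h",),
    "SO2": ("mean_24h", "max_1h"),
    "NO2": ("max_1h",),
    "CO": ("max_rolling_8h",),
    "O3": ("max_rolling_8h",),
}

_STAT_FUNCS = {
    "mean_24h": daily_mean_24h,
    "max_1h": daily_max_1h,
    "max_rolling_8h": max_rolling_8h,
}


def compute_daily_statistics(
    pollutant: str,
    series: HourlySeries,
    dates=None,
    min_valid_hours: int = 18,
    min_window_valid_hours: int = 6,
) -> list[DailyStatistic]:
    """All statistics for one pollutant's local-time series.

    ``dates`` defaults to every local date the series touches. Statistics
    suppressed by the completeness rule are returned with ``value`` NaN, so
    partial first/last local days are visible, not silently dropped.
    """
    if pollutant not in STATISTICS_BY_POLLUTANT:
        raise ValueError(f"unknown pollutant {pollutant!r}")
    if dates is None:
        dates = sorted({ts.date() for ts in series.values.index})
    out: list[DailyStatistic] = []
    for date in dates:
        for stat in STATISTICS_BY_POLLUTANT[pollutant]:
            if stat == "max_rolling_8h":
                out.append(
                    max_rolling_8h(
                        series, date,
                        min_valid_hours=min_valid_hours,
                        min_window_valid_hours=min_window_valid_hours,
                    )
                )
            else:
                out.append(_STAT_FUNCS[stat](series, date, min_valid_hours=min_valid_hours))
    return out
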