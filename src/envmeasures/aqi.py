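"""Air Quality Index computation from daily pollutant statistics.

The AQI maps a daily concentration statistic onto a 0-500 index via
piecewise-linear interpolation between published breakpoints:

    AQI = round((aqi_hi - aqi_lo) / (conc_hi - conc_lo) * (C - conc_lo) + aqi_lo)

where ``C`` is the concentration truncated (not rounded) to the pollutant's
reporting precision, the round is half-up to an integer, and the breakpoint
row is the one whose ``[conc_lo, conc_hi]`` interval contains ``C``. Six
health-concern categories partition the scale at AQI 50/100/150/200/300.
Concentrations above the highest breakpoint ("beyond the AQI") are assigned
the highest category with the scale maximum of 500 and a flag.

Breakpoint tables are versioned data fixtures; ``load_breakpoints()``
returns the shipped default (2018 technical-document vintage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .aq import DailyStatistic
from .grids import UnitError

__all__ = [
    "BreakpointTable",
    "AqiResult",
    "load_breakpoints",
    "truncate_concentration",
    "compute_aqi",
    "cap_beyond_aqi",
    "CATEGORIES",
]

AQI_MAX = 500

CATEGORIES = (
    "Good",
    "Moderate",
    "Unhealthy for Sensitive Groups",
    "Unhealthy",
    "Very Unhealthy",
    "Hazardous",
)

# mixing-ratio conversions between a statistic's units and a table's units
_UNIT_FACTORS = {("ppb", "ppm"): 1e-3, ("ppm", "ppb"): 1e3}


@dataclass
class BreakpointTable:
    """Ordered breakpoint rows per (pollutant, statistic) plus precisions."""

    rows: pd.DataFrame
    version: str

    def __post_init__(self) -> None:
        self.rows = self.rows.sort_values(["pollutant", "conc_lo"]).reset_index(drop=True)
        for (pol, stat), grp in self.rows.groupby(["pollutant", "statistic"]):
            unit = 10.0 ** -grp["precision"].iloc[0]
            lo, hi = grp["conc_lo"].to_numpy(), grp["conc_hi"].to_numpy()
            if not np.allclose(lo[1:], hi[:-1] + unit, atol=unit * 1e-6):
                raise ValueError(f"{pol}/{stat}: breakpoint rows are not contiguous")
            if not np.all(grp["aqi_lo"].to_numpy()[1:] == grp["aqi_hi"].to_numpy()[:-1] + 1):
                raise ValueError(f"{pol}/{stat}: AQI ranges are not contiguous")
            if not set(grp["category"]) <= set(CATEGORIES):
                raise ValueError(f"{pol}/{stat}: unknown category name")

    def pollutants(self) -> list[str]:
        return sorted(self.rows["pollutant"].unique())

    def for_pollutant(self, pollutant: str) -> pd.DataFrame:
        grp = self.rows[self.rows["pollutant"] == pollutant]
        if grp.empty:
            raise ValueError(f"no breakpoints for pollutant {pollutant!r}")
        return grp

    def statistic(self, pollutant: str) -> str:
        """Which daily statistic feeds the AQI for this pollutant."""
        return str(self.for_pollutant(pollutant)["statistic"].iloc[0])

    def precision(self, pollutant: str) -> int:
        return int(self.for_pollutant(pollutant)["precision"].iloc[0])

    def units(self, pollutant: str) -> str:
        return str(self.for_pollutant(pollutant)["units"].iloc[0])


def load_breakpoints(version: str = "2018") -> BreakpointTable:
    """Load a shipped breakpoint-table fixture by version."""
    name = f"aqi_breakpoints_{version}.csv"
    ref = resources.files("envmeasures.data").joinpath(name)
    if not ref.is_file():
        raise ValueError(f"no breakpoint table version {version!r}")
    with ref.open() as fh:
        rows = pd.read_csv(fh)
    return BreakpointTable(rows=rows, version=version)


@dataclass
class AqiResult:
    """AQI value + category for one daily statistic."""

    aqi_value: int
    category: str
    beyond_flag: bool
    input_concentration: float
    pollutant: str
    statistic: str


def truncate_concentration(value: float, pollutant: str, table: BreakpointTable) -> float:
    """Truncate (never round) to the pollutant's reporting precision.

    Decimal string arithmetic avoids binary-float artifacts such as
    35.4 * 10 == 353.999... truncating to 35.3.
    """
    if value < 0:
        raise ValueError("concentration must be >= 0")
    p = table.precision(pollutant)
    q = Decimal(1).scaleb(-p)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_DOWN))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _convert(value: float, from_units: str, to_units: str) -> float:
    if from_units == to_units:
        return value
    factor = _UNIT_FACTORS.get((from_units, to_units))
    if factor is None:
        raise UnitError(f"cannot convert {from_units} to {to_units}")
    return value * factor


def cap_beyond_aqi(value: float, pollutant: str, table: BreakpointTable) -> AqiResult:
    """Beyond-scale concentration → highest category, scale maximum, flag."""
    return AqiResult(
        aqi_value=AQI_MAX,
        category=CATEGORIES[-1],
        beyond_flag=True,
        input_concentration=value,
        pollutant=pollutant,
        statistic=table.statistic(pollutant),
    )


def compute_aqi(stat: DailyStatistic, table: BreakpointTable) -> AqiResult | None:
    """AQI for one daily statistic; ``None`` when the statistic is missing.

    The statistic's units are converted to the table's (ppb <-> ppm) before
    truncation. Statistics whose type does not feed AQI for the pollutant
    (e.g. the SO2 24-h mean, emitted as a concentration measure only) raise
    ``ValueError``.
    """
    if stat.is_missing:
        return None
    pollutant = stat.pollutant
    if stat.statistic != table.statistic(pollutant):
        raise ValueError(
            f"{pollutant} AQI uses {table.statistic(pollutant)}, got {stat.statistic}"
        )
    value = _convert(stat.value, stat.units, table.units(pollutant))
    trunc = truncate_concentration(value, pollutant, table)
    grp = table.for_pollutant(pollutant)
    top_hi = float(grp["conc_hi"].iloc[-1])
    if trunc > top_hi:
        return cap_beyond_aqi(trunc, pollutant, table)
    row = grp[(grp["conc_lo"] <= trunc) & (trunc <= grp["conc_hi"])]
    if row.empty:
        raise ValueError(f"{pollutant}: no breakpoint row contains {trunc}")
    r = row.iloc[0]
    # Decimal keeps the interpolation exact at half-integer ties
    # (e.g. CO 3.3/4.4 * 50 is exactly 37.5, which binary floats miss)
    c = Decimal(repr(trunc))
    lo, hi = Decimal(repr(float(r["conc_lo"]))), Decimal(repr(float(r["conc_hi"])))
    raw = (Decimal(int(r["aqi_hi"] - r["aqi_lo"])) * (c - lo)) / (hi - lo) + int(r["aqi_lo"])
    aqi = _round_half_up(float(raw))
    return AqiResult(
        aqi_value=aqi,
        category=str(r["category"]),
        beyond_flag=False,
        input_concentration=trunc,
        pollutant=pollutant,
        statistic=stat.statistic,
    )
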