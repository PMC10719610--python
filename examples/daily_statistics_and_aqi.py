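"""From an hourly ozone series to a daily statistic and its AQI category.

Ozone's daily surveillance statistic is the maximum 8-hour rolling mean:
24 candidate windows start at each local hour (reading up to 7 hours into
the next day), each needs at least 6 of its 8 hours, and the day itself
needs at least 18 of 24 valid hours. The statistic then maps to the 0-500
Air Quality Index by linear interpolation between published breakpoints.
"""

import numpy as np
import pandas as pd

import envmeasures as em

# a smog-like afternoon peak: 30 ppb overnight, rising to ~95 ppb at 15:00
hours = np.arange(31)  # one local day plus the 7 spill-over hours
values = 30 + 65 * np.exp(-0.5 * ((hours % 24 - 15) / 3.0) ** 2)
series = em.HourlySeries(
    "06037", "O3",
    pd.Series(values, index=pd.date_range("2023-06-01", periods=31, freq="h")),
    "ppb", timezone="local",
)

stat = em.max_rolling_8h(series, "2023-06-01")
print(f"peak hourly ozone        : {values.max():.1f} ppb")
print(f"max 8-h rolling mean     : {stat.value:.2f} ppb "
      f"(completeness {stat.completeness:.0%})")

table = em.load_breakpoints()
result = em.compute_aqi(stat, table)
print(f"AQI                      : {result.aqi_value} ({result.category})")
print("  the 8-h mean smooths the afternoon peak; the AQI category is what")
print("  a surveillance dashboard would display for this jurisdiction-day")
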