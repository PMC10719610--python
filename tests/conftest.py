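import numpy as np
import pandas as pd
import pytest

from envmeasures import FieldSpec, GeographySpec, GriddedField, HourlySeries, load_breakpoints

START = "2023-06-01"


def make_field(values, variable="X", units="ppb", origin=(0.0, 0.0), cell=0.5,
               start=START):
    """GriddedField from a raw (time, lat, lon) array with a regular grid."""
    values = np.asarray(values, dtype=float)
    nt, nlat, nlon = values.shape
    return GriddedField(
        variable=variable,
        values=values,
        units=units,
        timestamps=pd.date_range(start, periods=nt, freq="h"),
        lons=origin[0] + cell * (np.arange(nlon) + 0.5),
        lats=origin[1] + cell * (np.arange(nlat) + 0.5),
    )


def make_series(values, jurisdiction="J1", pollutant="O3", units="ppb",
                start=START, timezone="local"):
    """Local-time hourly series; NaN entries mark missing hours."""
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=len(values), freq="h")
    return HourlySeries(jurisdiction, pollutant, pd.Series(values, index=idx),
                        units, timezone=timezone)


@pytest.fixture(scope="session")
def breakpoints():
    return load_breakpoints()


@pytest.fixture
def small_geography():
    """2x2 counties, 2 tracts each, 4 blocks per tract, in degrees."""
    from envmeasures import generate_geography
    spec = GeographySpec(
        n_counties_x=2, n_counties_y=2, tracts_per_county=2, blocks_per_tract=4,
        county_width=1.0, county_height=1.0, seed=42,
    )
    return generate_geography(spec)


@pytest.fixture
def meters_geography():
    """2x1 counties in planar meters, sized to a 250 m flood raster."""
    from envmeasures import generate_geography
    spec = GeographySpec(
        n_counties_x=2, n_counties_y=1, tracts_per_county=2, blocks_per_tract=2,
        county_width=6250.0, county_height=12500.0, coord_units="meters", seed=7,
    )
    return generate_geography(spec)


@pytest.fixture
def constant_field_spec():
    return FieldSpec(
        n_lon=3, n_lat=3, cell_size_deg=0.5, origin_lon=0.0, origin_lat=0.0,
        n_hours=24, variables={"O3": "ppb"}, baseline={"O3": 10.0}, seed=0,
    )
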