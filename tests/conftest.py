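import numpy as np
import pandas as pd
import pytest

from dzudrisk import (
    ClimatePanel, SimulationConfig, build_risk_panel, simulate_panel,
)


@pytest.fixture(scope="session")
def small_sim():
    """Three-region synthetic bundle with the default generative truth."""
    return simulate_panel(SimulationConfig(n_regions=3), seed=1)


@pytest.fixture(scope="session")
def small_panels(small_sim):
    return {
        region: build_risk_panel(
            small_sim.climate, small_sim.census, small_sim.socio, region)
        for region in ("R01", "R02", "R03")
    }


@pytest.fixture(scope="session")
def default_sim():
    """Full 21-region, 2000-2014 synthetic bundle (the study-scale setting)."""
    return simulate_panel(SimulationConfig(), seed=0)


@pytest.fixture(scope="session")
def default_panels(default_sim):
    regions = sorted(default_sim.census["region"].unique())
    return {
        region: build_risk_panel(
            default_sim.climate, default_sim.census, default_sim.socio, region)
        for region in regions
    }


def make_flat_climate(years=(1980, 2012), baseline=(1981, 2010),
                      region="A", precip_by_month=None, temp_by_month=None,
                      snow_by_month=None):
    """Climate panel equal to its own climatology (every year identical)."""
    months = np.arange(1, 13)
    p = np.asarray(precip_by_month if precip_by_month is not None
                   else 10.0 + 5.0 * (months >= 6) * (months <= 8), float)
    t = np.asarray(temp_by_month if temp_by_month is not None
                   else -20.0 + 4.0 * np.abs(months - 7.0) * -1 + 25.0, float)
    s = np.asarray(snow_by_month if snow_by_month is not None
                   else np.where((months <= 3) | (months >= 11), 12.0, 0.0),
                   float)
    rows = []
    for year in range(years[0], years[1] + 1):
        for m in months:
            rows.append({"region": region, "year": year, "month": int(m),
                         "tmean_c": t[m - 1], "precip_mm": p[m - 1],
                         "snowdepth_cm": s[m - 1]})
    return ClimatePanel(pd.DataFrame(rows), baseline=baseline)
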