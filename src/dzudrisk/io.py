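"""CSV schemas: read, validate and write the analysis input tables.

All tables are UTF-8 CSV, one record per row:

* ``climate.csv``: region, year, month, tmean_c, precip_mm, snowdepth_cm
* ``census.csv``: region, year, camels, horses, cattle, sheep, goats,
  deaths_camels, ..., deaths_goats (December census head counts and the
  cold-season deaths recorded under the season's label year)
* ``socio.csv``: region, year, the socioeconomic indicator columns and the
  eight raw feed components (see :mod:`dzudrisk.indices`)
* ``mortality.csv``: region, year, deaths_su, pop_pre_su,
  rel_mortality_pct, loss_pre_su (generator output convenience table)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import DataValidationError
from .indices import (
    CLIMATE_VARS, ClimatePanel, FEED_COMPONENTS, SOCIO_INDICATORS, SPECIES,
)

CENSUS_COLUMNS = ["region", "year"] + list(SPECIES) + \
    [f"deaths_{sp}" for sp in SPECIES]
SOCIO_COLUMNS = ["region", "year"] + list(SOCIO_INDICATORS) + \
    list(FEED_COMPONENTS)
_HERD_CLASS_FRACTIONS = ["l_le100", "l_101_200", "l_201_500",
                         "l_501_999", "l_ge1000"]
_FRACTIONS = ["h_young", "h_exp", "tv"] + _HERD_CLASS_FRACTIONS


def _check_columns(frame: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataValidationError(f"{what} missing columns: {missing}")


def read_climate(path, baseline: tuple[int, int] = (1981, 2010)) -> ClimatePanel:
    """Load climate.csv; schema and invariants are checked by ClimatePanel."""
    frame = pd.read_csv(path)
    _check_columns(frame, ["region", "year", "month", *CLIMATE_VARS],
                   "climate table")
    return ClimatePanel(frame, baseline=baseline)


def write_climate(panel: ClimatePanel, path) -> None:
    panel.data.to_csv(path, index=False)


def read_census(path, validate_deaths: bool = False) -> pd.DataFrame:
    """Load census.csv; optionally require deaths <= census per species."""
    frame = pd.read_csv(path)
    _check_columns(frame, CENSUS_COLUMNS, "census table")
    for sp in SPECIES:
        for col in (sp, f"deaths_{sp}"):
            bad = frame[frame[col] < 0]
            if not bad.empty:
                row = bad.iloc[0]
                raise DataValidationError(
                    f"negative count {col!r} for region {row['region']!r} "
                    f"year {int(row['year'])}")
        if validate_deaths:
            bad = frame[frame[f"deaths_{sp}"] > frame[sp]]
            if not bad.empty:
                row = bad.iloc[0]
                raise DataValidationError(
                    f"deaths exceed census for species {sp!r}, region "
                    f"{row['region']!r} year {int(row['year'])}")
    return frame


def read_socio(path, fraction_sum_tol: float = 0.05) -> pd.DataFrame:
    """Load socio.csv; fractions in [0,1], feed components >= 0, and the
    herd-size-class fractions summing to at most 1 + tolerance."""
    frame = pd.read_csv(path)
    _check_columns(frame, SOCIO_COLUMNS, "socioeconomic table")
    for col in _FRACTIONS:
        bad = frame[(frame[col] < 0) | (frame[col] > 1)]
        if not bad.empty:
            row = bad.iloc[0]
            raise DataValidationError(
                f"fraction {col!r} outside [0,1] for region {row['region']!r} "
                f"year {int(row['year'])}")
    sums = frame[_HERD_CLASS_FRACTIONS].sum(axis=1)
    bad = frame[sums > 1 + fraction_sum_tol]
    if not bad.empty:
        row = bad.iloc[0]
        raise DataValidationError(
            f"herd-size-class fractions sum above 1 for region "
            f"{row['region']!r} year {int(row['year'])}")
    for col in list(FEED_COMPONENTS) + ["trucks", "shelter", "gdp"]:
        bad = frame[frame[col] < 0]
        if not bad.empty:
            row = bad.iloc[0]
            raise DataValidationError(
                f"negative value {col!r} for region {row['region']!r} "
                f"year {int(row['year'])}")
    return frame


def write_tables(simulated, outdir) -> dict[str, Path]:
    """Write the four generated tables of a SimulatedPanel to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "climate": outdir / "climate.csv",
        "census": outdir / "census.csv",
        "socio": outdir / "socio.csv",
        "mortality": outdir / "mortality.csv",
    }
    simulated.climate.data.to_csv(paths["climate"], index=False)
    simulated.census.to_csv(paths["census"], index=False)
    simulated.socio.to_csv(paths["socio"], index=False)
    simulated.mortality.to_csv(paths["mortality"], index=False)
    return paths
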