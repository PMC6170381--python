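"""Hazard and vulnerability indicator construction for dzud risk analysis.

The modelling unit is the region (Mongolian *aimag*) and the cold season.
A cold season spanning October of year Y-1 through April of year Y is
labelled Y — the year that contains the spring losses.  Under this
labelling:

* the drought index ``P_6-8`` for season Y is the precipitation anomaly of
  the *preceding* summer, June–August of year Y-1 (drought weakens animals
  and reduces hay/forage before the winter);
* the winter temperature anomaly ``T_11-2`` averages November and December
  of Y-1 with January and February of Y;
* the snow hazard ``SD`` is the monthly maximum snow depth, by default for
  January of Y;
* ``POP_pre`` is the December census of year Y-1 converted to sheep units,
  i.e. the herd standing on January 1 of the loss year.

Anomalies are taken against a baseline climatology window carried by the
:class:`ClimatePanel` (conventionally 1981–2010).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, PanelError

logger = logging.getLogger(__name__)

# Sheep-unit (SU) conversion: feed-requirement equivalents of each species.
SU_RATES: dict[str, float] = {
    "camels": 5.0,
    "horses": 7.0,
    "cattle": 6.0,
    "sheep": 1.0,
    "goats": 0.9,
}

SPECIES: tuple[str, ...] = tuple(SU_RATES)

# Weights of the prepared hay/forage composite (mass per SU of each
# component, summed with these coefficients).
HAY_FORAGE_COEFFS: dict[str, float] = {
    "hay": 0.45,
    "planted_feed": 0.35,
    "silage_feed": 0.25,
    "artificial_feed": 1.0,   # artificial (concentrated) feed and mineral salt
    "potato_scraps": 0.22,    # potatoes and vegetable scraps
    "unripe_wheat": 0.9,      # imperfectly ripened wheat
    "residuals": 0.4,
    "straw": 0.25,
}

FEED_COMPONENTS: tuple[str, ...] = tuple(HAY_FORAGE_COEFFS)

#: Socioeconomic indicator columns expected in a socio table, beside the
#: raw feed components.
SOCIO_INDICATORS: tuple[str, ...] = (
    "h_young",      # fraction of herders aged 16-34
    "h_exp",        # fraction aged 35-59 (men) / 35-54 (women)
    "l_le100",      # household fractions by herd-size class
    "l_101_200",
    "l_201_500",
    "l_501_999",
    "l_ge1000",
    "trucks",       # cars and tractors per herder household
    "tv",           # fraction of households with a TV
    "shelter",      # warm/roofed barns per household
    "gdp",          # real GDP per capita, 10^3 Tugrug
)

#: All candidate mortality-risk indicators screened in the analysis.
CANDIDATE_INDICATORS: tuple[str, ...] = (
    "pop_pre", "loss_pre",
) + SOCIO_INDICATORS + ("hay_forage",)

CLIMATE_VARS: tuple[str, ...] = ("tmean_c", "precip_mm", "snowdepth_cm")


# ---------------------------------------------------------------------------
# Panel containers
# ---------------------------------------------------------------------------

@dataclass
class ClimatePanel:
    """Monthly climate records per region with a baseline climatology window.

    Parameters
    ----------
    data :
        Long-format frame with columns ``region, year, month, tmean_c,
        precip_mm, snowdepth_cm`` — one record per region-year-month.
    baseline :
        Inclusive ``(first, last)`` year range used for climatological
        anomalies.
    """

    data: pd.DataFrame
    baseline: tuple[int, int]

    def __post_init__(self) -> None:
        required = ["region", "year", "month"] + list(CLIMATE_VARS)
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise DataValidationError(f"climate table missing columns: {missing}")
        if self.data.duplicated(["region", "year", "month"]).any():
            raise DataValidationError("duplicate region-year-month climate records")
        if (self.data["precip_mm"] < 0).any():
            raise DataValidationError("negative precipitation in climate table")
        if (self.data["snowdepth_cm"] < 0).any():
            raise DataValidationError("negative snow depth in climate table")
        b0, b1 = self.baseline
        if b1 < b0:
            raise DataValidationError(f"empty baseline window {self.baseline}")
        self._grids: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}

    @property
    def regions(self) -> list[str]:
        return sorted(self.data["region"].unique())

    def _grid(self, var: str, region: str) -> tuple[np.ndarray, np.ndarray]:
        """(years, years x 12 array) of `var` for one region; NaN = missing."""
        cache = self._grids.setdefault(var, {})
        if region not in cache:
            sub = self.data[self.data["region"] == region]
            if sub.empty:
                raise DataValidationError(f"region {region!r} not in climate table")
            piv = sub.pivot(index="year", columns="month", values=var)
            piv = piv.reindex(columns=range(1, 13))
            cache[region] = (piv.index.to_numpy(), piv.to_numpy(dtype=float))
        return cache[region]

    def value(self, var: str, region: str, year: int, month: int) -> float:
        years, grid = self._grid(var, region)
        idx = np.searchsorted(years, year)
        if idx >= len(years) or years[idx] != year:
            return np.nan
        return grid[idx, month - 1]


def _require(values: dict[tuple[int, int], float], what: str, region: str) -> None:
    missing = [ym for ym, v in values.items() if np.isnan(v)]
    if missing:
        raise DataValidationError(
            f"{what} for region {region!r}: missing months {sorted(missing)}"
        )


# ---------------------------------------------------------------------------
# Hazard indices
# ---------------------------------------------------------------------------

def drought_index(climate: ClimatePanel, region: str, summer_year: int) -> float:
    """Precipitation anomaly percentage for June–August (``P_6-8``).

    ``100 * (P_sum - P_bar) / P_bar`` where ``P_sum`` is total Jun–Aug
    precipitation of ``summer_year`` and ``P_bar`` the baseline mean of the
    same seasonal total.  Bounded below by -100 % since precipitation is
    non-negative.
    """
    months = (6, 7, 8)
    vals = {(summer_year, m): climate.value("precip_mm", region, summer_year, m)
            for m in months}
    _require(vals, "drought index", region)
    p_sum = float(sum(vals.values()))

    b0, b1 = climate.baseline
    years, grid = climate._grid("precip_mm", region)
    mask = (years >= b0) & (years <= b1)
    jja = grid[mask][:, 5:8]
    complete = ~np.isnan(jja).any(axis=1)
    if not complete.any():
        raise DataValidationError(
            f"no complete Jun-Aug baseline season for region {region!r}"
        )
    p_bar = float(jja[complete].sum(axis=1).mean())
    if p_bar <= 0:
        raise DataValidationError(
            f"zero baseline Jun-Aug precipitation for region {region!r}"
        )
    return 100.0 * (p_sum - p_bar) / p_bar


def _winter_composite(climate: ClimatePanel, region: str, year: int) -> float:
    """Mean Nov/Dec(year-1) and Jan/Feb(year) temperature; NaN if incomplete."""
    vals = [
        climate.value("tmean_c", region, year - 1, 11),
        climate.value("tmean_c", region, year - 1, 12),
        climate.value("tmean_c", region, year, 1),
        climate.value("tmean_c", region, year, 2),
    ]
    return float(np.mean(vals))  # NaN-propagating on purpose


def winter_temp_anomaly(climate: ClimatePanel, region: str,
                        cold_season_year: int) -> float:
    """November–February mean temperature anomaly (``T_11-2``), additive °C.

    The composite for season Y is the mean of the four monthly means
    Nov(Y-1), Dec(Y-1), Jan(Y), Feb(Y); the anomaly subtracts the baseline
    mean of the same composite.
    """
    y = cold_season_year
    vals = {
        (y - 1, 11): climate.value("tmean_c", region, y - 1, 11),
        (y - 1, 12): climate.value("tmean_c", region, y - 1, 12),
        (y, 1): climate.value("tmean_c", region, y, 1),
        (y, 2): climate.value("tmean_c", region, y, 2),
    }
    _require(vals, "winter temperature anomaly", region)
    composite = float(np.mean(list(vals.values())))

    b0, b1 = climate.baseline
    baseline_vals = [_winter_composite(climate, region, yy)
                     for yy in range(b0, b1 + 1)]
    baseline_vals = [v for v in baseline_vals if not np.isnan(v)]
    if not baseline_vals:
        raise DataValidationError(
            f"no complete Nov-Feb baseline winter for region {region!r}"
        )
    return composite - float(np.mean(baseline_vals))


_SNOW_WINDOWS = {
    # month offsets relative to the cold-season label year Y:
    # (year offset, month)
    "january": ((0, 1),),
    "nov-mar": ((-1, 11), (-1, 12), (0, 1), (0, 2), (0, 3)),
}


def snow_hazard(climate: ClimatePanel, region: str, cold_season_year: int,
                window: str = "january", anomaly: bool = False) -> float:
    """Maximum monthly snow depth (``SD``, cm) over the chosen window.

    The default window is January of the loss year — the month of peak snow
    depth and the strongest association with losses; ``"nov-mar"`` takes the
    maximum over November(Y-1)–March(Y).  With ``anomaly=True`` the baseline
    mean of the same windowed maximum is subtracted.
    """
    if window not in _SNOW_WINDOWS:
        raise DataValidationError(
            f"unknown snow window {window!r}; valid: {sorted(_SNOW_WINDOWS)}"
        )
    offsets = _SNOW_WINDOWS[window]

    def windowed_max(year: int) -> float:
        vals = [climate.value("snowdepth_cm", region, year + dy, m)
                for dy, m in offsets]
        return float(np.max(vals))  # NaN-propagating

    vals = {(cold_season_year + dy, m):
            climate.value("snowdepth_cm", region, cold_season_year + dy, m)
            for dy, m in offsets}
    _require(vals, f"snow hazard ({window})", region)
    sd = windowed_max(cold_season_year)

    if not anomaly:
        return sd
    b0, b1 = climate.baseline
    baseline_vals = [windowed_max(yy) for yy in range(b0, b1 + 1)]
    baseline_vals = [v for v in baseline_vals if not np.isnan(v)]
    if not baseline_vals:
        raise DataValidationError(
            f"no complete baseline snow window for region {region!r}"
        )
    return sd - float(np.mean(baseline_vals))


# ---------------------------------------------------------------------------
# Census-derived quantities
# ---------------------------------------------------------------------------

def to_sheep_units(counts: Mapping[str, float] | pd.Series) -> float:
    """Convert per-species head counts to sheep units.

    SU = 5·camels + 7·horses + 6·cattle + 1·sheep + 0.9·goats; linear and
    exact.  Unknown species names raise; missing species count as zero.
    """
    total = 0.0
    for name, count in dict(counts).items():
        if name not in SU_RATES:
            raise DataValidationError(
                f"unknown species {name!r}; valid: {list(SU_RATES)}"
            )
        if count < 0:
            raise DataValidationError(f"negative head count for species {name!r}")
        total += SU_RATES[name] * float(count)
    return total


def relative_mortality(deaths_su: float, jan1_total_su: float) -> float:
    """Cold-season deaths as a percentage of the January-1 herd, both in SU."""
    if jan1_total_su <= 0:
        raise DataValidationError(
            f"non-positive January-1 herd total ({jan1_total_su}) in "
            "relative mortality"
        )
    if deaths_su < 0:
        raise DataValidationError("negative deaths in relative mortality")
    return 100.0 * deaths_su / jan1_total_su


def hay_forage_index(components: Mapping[str, float] | pd.Series) -> float:
    """Weighted prepared hay/forage composite (mass per SU).

    Components are summed with fixed coefficients: 0.45 hay, 0.35 planted
    feed, 0.25 silage feed, 1.0 artificial feed & mineral salt, 0.22
    potatoes/vegetable scraps, 0.9 imperfectly ripened wheat, 0.4 residuals,
    0.25 straw.
    """
    total = 0.0
    for name, mass in dict(components).items():
        if name not in HAY_FORAGE_COEFFS:
            raise DataValidationError(
                f"unknown feed component {name!r}; valid: {list(HAY_FORAGE_COEFFS)}"
            )
        if mass < 0:
            raise DataValidationError(f"negative mass for feed component {name!r}")
        total += HAY_FORAGE_COEFFS[name] * float(mass)
    return total


# ---------------------------------------------------------------------------
# Risk panel
# ---------------------------------------------------------------------------

@dataclass
class RiskPanel:
    """Per-region, cold-season-year table of deaths and aligned predictors.

    ``data`` is indexed by the cold-season label year and carries: deaths in
    SU (``deaths_su``), the integer deaths used by the count likelihood
    (``deaths``), relative mortality (%), the three hazard indices
    (``p68, t112, sd``), ``pop_pre`` and ``loss_pre`` (SU), and all candidate
    vulnerability indicators including the ``hay_forage`` composite.
    """

    region: str
    data: pd.DataFrame
    dropped: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)


def _census_su(row: pd.Series, death: bool = False) -> float:
    prefix = "deaths_" if death else ""
    return to_sheep_units({sp: row[prefix + sp] for sp in SPECIES})


def build_risk_panel(
    climate: ClimatePanel,
    census: pd.DataFrame,
    socio: pd.DataFrame,
    region: str,
    years: tuple[int, int] = (2000, 2014),
    snow_window: str = "january",
    snow_anomaly: bool = False,
    rounding: str = "nearest",
) -> RiskPanel:
    """Assemble the modelling panel for one region.

    One row per cold-season year Y in ``years`` with deaths of season Y, the
    lagged hazard indices (summer drought of Y-1; Nov(Y-1)–Feb(Y) cold;
    January(Y) snow), ``pop_pre``/``loss_pre`` from the December census of
    Y-1, and pre-winter socioeconomic indicators of year Y-1.  Rows with any
    missing field are dropped listwise and logged.  SU death totals are
    rounded to the nearest integer (or floored with ``rounding="floor"``)
    for the count likelihood; the un-rounded total is kept alongside.
    """
    if rounding not in ("nearest", "floor"):
        raise DataValidationError(f"unknown rounding rule {rounding!r}")
    cen = census[census["region"] == region].set_index("year")
    soc = socio[socio["region"] == region].set_index("year")

    rows: list[dict] = []
    dropped: list[tuple[int, str]] = []
    for year in range(years[0], years[1] + 1):
        try:
            if year not in cen.index:
                raise DataValidationError(f"no census record for year {year}")
            if year - 1 not in cen.index:
                raise DataValidationError(f"no census record for year {year - 1}")
            if year - 1 not in soc.index:
                raise DataValidationError(
                    f"no socioeconomic record for year {year - 1}"
                )
            crow, prow, srow = cen.loc[year], cen.loc[year - 1], soc.loc[year - 1]
            deaths_su = _census_su(crow, death=True)
            pop_pre = _census_su(prow)
            row = {
                "year": year,
                "deaths_su": deaths_su,
                "deaths": int(np.floor(deaths_su) if rounding == "floor"
                              else np.rint(deaths_su)),
                "pop_pre": pop_pre,
                "loss_pre": _census_su(prow, death=True),
                "rel_mortality": relative_mortality(deaths_su, pop_pre),
                "p68": drought_index(climate, region, year - 1),
                "t112": winter_temp_anomaly(climate, region, year),
                "sd": snow_hazard(climate, region, year,
                                  window=snow_window, anomaly=snow_anomaly),
                "hay_forage": hay_forage_index(
                    {c: srow[c] for c in FEED_COMPONENTS}),
            }
            for ind in SOCIO_INDICATORS:
                row[ind] = float(srow[ind])
            if any(np.isnan(v) for k, v in row.items() if k != "year"):
                bad = [k for k, v in row.items() if k != "year" and np.isnan(v)]
                raise DataValidationError(f"missing fields {bad}")
            rows.append(row)
        except DataValidationError as exc:
            logger.warning("region %s, season %d dropped: %s", region, year, exc)
            dropped.append((year, str(exc)))

    if len(rows) < 3:
        raise PanelError(
            f"region {region!r}: only {len(rows)} complete cold-season rows "
            f"in {years}; need >=3 to fit a model"
        )
    data = pd.DataFrame(rows).set_index("year")
    return RiskPanel(region=region, data=data, dropped=dropped)
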