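"""Simulation configuration for synthetic dzud-risk panels.

The defaults emulate a Mongolia-like setting: 21 regions (aimags) with a
latitudinal climate gradient, a 1971–2014 monthly climate record with a
1981–2010 baseline climatology, December herd censuses growing through the
record, and cold-season mortality for the 2000–2014 analysis window drawn
from a log-linear Poisson model on standardized hazard and vulnerability
predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .exceptions import ConfigurationError

#: Predictors that may carry a generative coefficient (the nine model
#: factors of the risk analysis).  loss_pre is deliberately absent: it is a
#: lagged outcome, emitted in panels but not part of the generative model.
GENERATIVE_PREDICTORS: tuple[str, ...] = (
    "p68", "t112", "sd", "pop_pre", "hay_forage",
    "h_exp", "trucks", "l_101_200", "gdp",
)


@dataclass
class HazardRegimes:
    """Probabilities and magnitudes of discrete hazard years.

    A drought year multiplies Jun–Aug precipitation by ``1 - drought_deficit``;
    a severe winter subtracts ``cold_anomaly_c`` °C from Nov–Feb temperatures
    and multiplies Nov–Mar snow depth by ``1 + snow_surplus``.  Regimes are
    drawn independently per region and year.
    """

    drought_prob: float = 0.25
    drought_deficit: float = 0.45
    severe_winter_prob: float = 0.25
    cold_anomaly_c: float = 3.0
    snow_surplus: float = 1.0

    def validate(self) -> None:
        for name in ("drought_prob", "severe_winter_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"hazard_regimes.{name} must be in [0,1]")
        if not 0.0 <= self.drought_deficit < 1.0:
            raise ConfigurationError(
                "hazard_regimes.drought_deficit must be in [0,1)")
        if self.snow_surplus < 0:
            raise ConfigurationError("hazard_regimes.snow_surplus must be >= 0")


@dataclass
class ClimateParams:
    """Per-region monthly climatology shapes and interannual variability.

    Region r (0-based, of R) sits at gradient position g = r/(R-1): annual
    mean temperature, summer rainfall and peak snow depth interpolate
    linearly between the listed south/dry (g=0) and north/wet (g=1)
    endpoints.  Monthly noise is additive normal for temperature and
    multiplicative (truncated at zero) for precipitation and snow.
    """

    temp_mean_south: float = 2.0        # °C annual mean, dry end
    temp_mean_north: float = -4.0       # °C annual mean, cold end
    temp_amplitude: float = 20.0        # °C seasonal half-range (Jul peak)
    temp_sd: float = 1.5                # interannual monthly SD, °C
    precip_annual_south: float = 110.0  # mm/yr
    precip_annual_north: float = 310.0
    precip_sd: float = 0.35             # relative SD of monthly totals
    snow_peak_south: float = 4.0        # cm January max depth
    snow_peak_north: float = 28.0
    snow_sd: float = 0.40               # relative SD of monthly depth

    def validate(self) -> None:
        for name in ("temp_sd", "precip_sd", "snow_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"climate_params.{name} must be >= 0")
        for name in ("precip_annual_south", "precip_annual_north",
                     "snow_peak_south", "snow_peak_north", "temp_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"climate_params.{name} must be >= 0")


@dataclass
class HerdParams:
    """Initial December herd sizes by species (head) and annual growth."""

    initial: dict[str, float] = field(default_factory=lambda: {
        "camels": 15_000, "horses": 120_000, "cattle": 130_000,
        "sheep": 900_000, "goats": 700_000,
    })
    growth_rate: float = 0.02      # mean annual multiplicative growth
    growth_sd: float = 0.03        # SD of annual growth shocks

    def validate(self) -> None:
        for sp, n in self.initial.items():
            if n < 0:
                raise ConfigurationError(
                    f"herd_params.initial[{sp!r}] must be >= 0")
        if self.growth_sd < 0:
            raise ConfigurationError("herd_params.growth_sd must be >= 0")


def _default_socio() -> dict[str, tuple[float, float]]:
    # indicator -> (mean, sd); fractions clipped to [0,1], others to >= 0
    return {
        "h_young": (0.30, 0.04),
        "h_exp": (0.45, 0.05),
        "l_le100": (0.45, 0.06),
        "l_101_200": (0.25, 0.04),
        "l_201_500": (0.18, 0.04),
        "l_501_999": (0.06, 0.02),
        "l_ge1000": (0.02, 0.01),
        "trucks": (0.50, 0.15),
        "tv": (0.60, 0.10),
        "shelter": (0.80, 0.20),
        "gdp": (1500.0, 350.0),         # 10^3 Tugrug per capita
        # raw feed components, kg per SU
        "hay": (60.0, 18.0),
        "planted_feed": (5.0, 2.0),
        "silage_feed": (2.0, 1.0),
        "artificial_feed": (3.0, 1.5),
        "potato_scraps": (1.0, 0.5),
        "unripe_wheat": (1.0, 0.5),
        "residuals": (2.0, 1.0),
        "straw": (3.0, 1.5),
    }


def _default_beta() -> dict[str, float]:
    # effect sizes on z-scored predictors: hazards raise deaths when the
    # summer is dry (negative p68), the winter cold (negative t112) or the
    # snow deep; overpopulation raises deaths; preparedness, experience,
    # transport and wealth lower them.
    return {
        "p68": -0.35,
        "t112": -0.20,
        "sd": 0.35,
        "pop_pre": 0.30,
        "hay_forage": -0.30,
        "h_exp": -0.10,
        "trucks": -0.10,
        "l_101_200": 0.10,
        "gdp": -0.10,
    }


@dataclass
class SimulationConfig:
    """Full specification of a synthetic region-panel experiment."""

    n_regions: int = 21
    years: tuple[int, int] = (1971, 2014)
    baseline_years: tuple[int, int] = (1981, 2010)
    analysis_years: tuple[int, int] = (2000, 2014)
    climate_params: ClimateParams = field(default_factory=ClimateParams)
    hazard_regimes: HazardRegimes = field(default_factory=HazardRegimes)
    herd_params: HerdParams = field(default_factory=HerdParams)
    socio_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_socio)
    beta0: float = 12.4                 # intercept: log expected SU deaths
    beta: dict[str, float] = field(default_factory=_default_beta)
    drought_hay_coupling: float = 0.0   # hay/forage response to drought z-score
    cap_deaths_at_herd: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be a positive integer")
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError(f"years range {self.years} is empty")
        b0, b1 = self.baseline_years
        if not (y0 <= b0 <= b1 <= y1):
            raise ConfigurationError(
                f"baseline_years {self.baseline_years} not within years {self.years}")
        a0, a1 = self.analysis_years
        if a1 < a0:
            raise ConfigurationError("analysis_years range is empty")
        if a0 - 2 < y0 or a1 > y1:
            # need summer of a0-2 and census of a0-2 for the spin-up season
            raise ConfigurationError(
                "analysis_years must start at least two years after the "
                "first simulated year (lagged predictors and spin-up season)")
        self.climate_params.validate()
        self.hazard_regimes.validate()
        self.herd_params.validate()
        for name, (mean, sd) in self.socio_params.items():
            if sd < 0:
                raise ConfigurationError(f"socio_params[{name!r}] SD must be >= 0")
        for name in self.beta:
            if name not in GENERATIVE_PREDICTORS:
                raise ConfigurationError(
                    f"beta[{name!r}] is not a generative predictor; "
                    f"valid: {list(GENERATIVE_PREDICTORS)}")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        known = cls.__dataclass_fields__
        unknown = [k for k in d if k not in known]
        if unknown:
            raise ConfigurationError(f"unknown configuration fields: {unknown}")
        for key, sub in (("climate_params", ClimateParams),
                         ("hazard_regimes", HazardRegimes),
                         ("herd_params", HerdParams)):
            if key in d and isinstance(d[key], Mapping):
                d[key] = sub(**d[key])
        for key in ("years", "baseline_years", "analysis_years"):
            if key in d:
                d[key] = tuple(d[key])
        if "socio_params" in d:
            d["socio_params"] = {k: tuple(v) for k, v in d["socio_params"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)
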