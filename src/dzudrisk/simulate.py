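"""Synthetic region-panel generator for the dzud risk analysis.

Generates, from a single seeded RNG, the four tables the analysis consumes:
a monthly climate record with drought and severe-winter regime years, annual
December herd censuses growing through the record, pre-winter socioeconomic
indicators, and cold-season death counts drawn from the log-linear Poisson
mortality model

    mu = exp(beta0 + sum_j beta_j z_j),    deaths ~ Poisson(mu)

where the z_j are the region's hazard and vulnerability predictors z-scored
against their own simulated distribution over the analysis window, so
configured coefficients are interpretable effect sizes and are directly
recoverable by the fitting machinery.

The generator computes its predictors with the same index functions the
analysis uses (:mod:`dzudrisk.indices`), and retains the standardized truth
(``SimulatedPanel.truth``) so that a rebuilt panel can be checked against
the generative state exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .exceptions import ConfigurationError
from . import indices
from .indices import (
    ClimatePanel, SPECIES, SU_RATES, FEED_COMPONENTS, SOCIO_INDICATORS,
    to_sheep_units, hay_forage_index,
)

# Fractions of annual precipitation falling in each calendar month
# (summer-concentrated, Jun-Aug ~60%).
_PRECIP_WEIGHTS = np.array(
    [.02, .02, .03, .05, .08, .17, .25, .18, .08, .05, .04, .03])
# Monthly snow depth relative to the January peak.
_SNOW_WEIGHTS = np.array(
    [1.0, 0.9, 0.6, 0.2, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.45, 0.75])

_FRACTION_INDICATORS = frozenset(
    {"h_young", "h_exp", "l_le100", "l_101_200", "l_201_500",
     "l_501_999", "l_ge1000", "tv"})


@dataclass
class SimulatedPanel:
    """Bundle of the four generated tables plus the generative truth."""

    climate: ClimatePanel
    census: pd.DataFrame
    socio: pd.DataFrame
    mortality: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def __iter__(self):
        # unpack as (climate, census, socio, mortality)
        yield from (self.climate, self.census, self.socio, self.mortality)


def _region_names(n: int) -> list[str]:
    return [f"R{i + 1:02d}" for i in range(n)]


def _gradient(i: int, n: int) -> float:
    return 0.5 if n == 1 else i / (n - 1)


def _simulate_climate(cfg: SimulationConfig, rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Monthly climate for all regions/years; also returns severe-winter flags
    per region indexed by cold-season label year."""
    cp, hz = cfg.climate_params, cfg.hazard_regimes
    y0, y1 = cfg.years
    years = np.arange(y0, y1 + 1)
    months = np.arange(1, 13)
    n_years = len(years)
    frames = []
    severe_flags: dict[str, np.ndarray] = {}
    for i, region in enumerate(_region_names(cfg.n_regions)):
        g = _gradient(i, cfg.n_regions)
        tmean = cp.temp_mean_south + g * (cp.temp_mean_north - cp.temp_mean_south)
        p_annual = (cp.precip_annual_south
                    + g * (cp.precip_annual_north - cp.precip_annual_south))
        snow_peak = cp.snow_peak_south + g * (cp.snow_peak_north - cp.snow_peak_south)

        t_clim = tmean + cp.temp_amplitude * np.cos(2 * np.pi * (months - 7) / 12)
        p_clim = p_annual * _PRECIP_WEIGHTS
        s_clim = snow_peak * _SNOW_WEIGHTS

        temp = t_clim + rng.normal(0.0, cp.temp_sd, size=(n_years, 12))
        precip = p_clim * np.maximum(
            0.0, 1.0 + rng.normal(0.0, cp.precip_sd, size=(n_years, 12)))
        snow = s_clim * np.maximum(
            0.0, 1.0 + rng.normal(0.0, cp.snow_sd, size=(n_years, 12)))

        drought = rng.random(n_years) < hz.drought_prob
        precip[drought, 5:8] *= (1.0 - hz.drought_deficit)

        # severe winters labelled by the season year Y (affects Nov/Dec of
        # Y-1 and Jan-Mar of Y); one flag per possible label y0+1..y1
        severe = rng.random(n_years) < hz.severe_winter_prob
        severe[0] = False  # season labelled y0 has no Nov/Dec record
        for k in np.flatnonzero(severe):
            yidx = k           # season label years[k]
            temp[yidx - 1, 10:12] -= hz.cold_anomaly_c      # Nov, Dec of Y-1
            temp[yidx, 0:2] -= hz.cold_anomaly_c            # Jan, Feb of Y
            snow[yidx - 1, 10:12] *= (1.0 + hz.snow_surplus)
            snow[yidx, 0:3] *= (1.0 + hz.snow_surplus)      # Jan-Mar of Y
        severe_flags[region] = severe

        frames.append(pd.DataFrame({
            "region": region,
            "year": np.repeat(years, 12),
            "month": np.tile(months, n_years),
            "tmean_c": temp.ravel(),
            "precip_mm": precip.ravel(),
            "snowdepth_cm": snow.ravel(),
        }))
    data = pd.concat(frames, ignore_index=True)
    return data, severe_flags


def _simulate_census(cfg: SimulationConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    hp = cfg.herd_params
    y0, y1 = cfg.years
    rows = []
    for i, region in enumerate(_region_names(cfg.n_regions)):
        scale = 0.5 + _gradient(i, cfg.n_regions)   # region herd size 0.5-1.5x
        heads = {sp: hp.initial[sp] * scale for sp in SPECIES}
        for year in range(y0, y1 + 1):
            row = {"region": region, "year": year}
            for sp in SPECIES:
                row[sp] = int(round(heads[sp]))
                row[f"deaths_{sp}"] = 0      # filled by the mortality draw
            rows.append(row)
            shock = rng.normal(hp.growth_rate, hp.growth_sd, size=len(SPECIES))
            for sp, s in zip(SPECIES, shock):
                heads[sp] = max(0.0, heads[sp] * (1.0 + s))
    return pd.DataFrame(rows)


def _simulate_socio(cfg: SimulationConfig, rng: np.random.Generator
                    ) -> pd.DataFrame:
    y0, y1 = cfg.years
    years = range(y0, y1 + 1)
    cols = list(SOCIO_INDICATORS) + list(FEED_COMPONENTS)
    herd_classes = ("l_le100", "l_101_200", "l_201_500",
                    "l_501_999", "l_ge1000")
    rows = []
    for region in _region_names(cfg.n_regions):
        for year in years:
            row = {"region": region, "year": year}
            for name in cols:
                mean, sd = cfg.socio_params[name]
                v = rng.normal(mean, sd)
                v = min(max(v, 0.0), 1.0) if name in _FRACTION_INDICATORS \
                    else max(v, 0.0)
                row[name] = v
            # herd-size-class household fractions must partition at most 1
            class_sum = sum(row[c] for c in herd_classes)
            if class_sum > 1.0:
                for c in herd_classes:
                    row[c] /= class_sum
            rows.append(row)
    return pd.DataFrame(rows)


def _apply_drought_hay_coupling(cfg: SimulationConfig, climate: ClimatePanel,
                                socio: pd.DataFrame) -> None:
    """Reduce prepared hay in drought summers (optional pathway).

    Hay recorded for year t is prepared during summer t; with coupling c the
    mean-hay-scaled adjustment is ``c * (P_6-8(t)/100) * mean_hay``, floored
    at zero.  Off (c = 0) by default.
    """
    c = cfg.drought_hay_coupling
    if c == 0.0:
        return
    mean_hay = cfg.socio_params["hay"][0]
    y0, _ = cfg.years
    for idx in socio.index:
        year = int(socio.at[idx, "year"])
        region = socio.at[idx, "region"]
        if year < y0 + 1:
            continue
        try:
            p68 = indices.drought_index(climate, region, year)
        except Exception:
            continue
        socio.at[idx, "hay"] = max(
            0.0, socio.at[idx, "hay"] + c * (p68 / 100.0) * mean_hay)


def _allocate_deaths(total_su: int, herd: dict[str, float]) -> dict[str, int]:
    """Split an integer SU death total into per-species head counts whose SU
    re-sum is exactly the total.

    Species receive deaths proportionally to their SU share of the herd;
    camel/horse/cattle head counts are floored to the proportional target,
    goats die in blocks of ten head (10 goats = 9 SU exactly, keeping the
    running SU total integral), and sheep (1 SU each) absorb the remainder.
    """
    herd_su = {sp: SU_RATES[sp] * herd[sp] for sp in SPECIES}
    total_herd = sum(herd_su.values())
    if total_herd <= 0:
        return {sp: (total_su if sp == "sheep" else 0) for sp in SPECIES}
    target = {sp: herd_su[sp] / total_herd * total_su for sp in SPECIES}
    out = {
        "camels": int(target["camels"] // 5),
        "horses": int(target["horses"] // 7),
        "cattle": int(target["cattle"] // 6),
        "goats": 10 * int(target["goats"] // 9),
    }
    assigned = (5 * out["camels"] + 7 * out["horses"] + 6 * out["cattle"]
                + 0.9 * out["goats"])
    out["sheep"] = int(round(total_su - assigned))
    return out


def simulate_panel(config: SimulationConfig | None = None,
                   seed: int | None = None) -> SimulatedPanel:
    """Generate a complete synthetic region-panel.

    Parameters
    ----------
    config :
        Simulation configuration; defaults describe a 21-region,
        1971–2014 record with a 2000–2014 analysis window.
    seed :
        Overrides ``config.seed`` when given.  Identical seed and config
        give byte-identical tables.
    """
    cfg = config if config is not None else SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    climate_data, _severe = _simulate_climate(cfg, rng)
    climate = ClimatePanel(climate_data, baseline=cfg.baseline_years)
    census = _simulate_census(cfg, rng)
    socio = _simulate_socio(cfg, rng)
    _apply_drought_hay_coupling(cfg, climate, socio)

    a0, a1 = cfg.analysis_years
    seasons = list(range(a0 - 1, a1 + 1))     # spin-up season a0-1 included
    analysis = [y for y in seasons if y >= a0]

    beta = dict(cfg.beta)
    for name in beta:
        if name not in set(indices.CANDIDATE_INDICATORS) | {"p68", "t112", "sd"}:
            raise ConfigurationError(f"beta names unknown predictor {name!r}")

    census_idx = census.set_index(["region", "year"])
    socio_idx = socio.set_index(["region", "year"])

    truth_rows = []
    mort_rows = []
    deaths_by_species: dict[tuple[str, int], dict[str, int]] = {}
    for region in _region_names(cfg.n_regions):
        # raw predictor paths over all seasons (spin-up + analysis)
        raw = {name: [] for name in beta}
        pop_pre_su = {}
        for y in seasons:
            prow = census_idx.loc[(region, y - 1)]
            srow = socio_idx.loc[(region, y - 1)]
            pop = to_sheep_units({sp: prow[sp] for sp in SPECIES})
            pop_pre_su[y] = pop
            vals = {
                "p68": indices.drought_index(climate, region, y - 1),
                "t112": indices.winter_temp_anomaly(climate, region, y),
                "sd": indices.snow_hazard(climate, region, y),
                "pop_pre": pop,
                "hay_forage": hay_forage_index(
                    {c: srow[c] for c in FEED_COMPONENTS}),
            }
            for ind in SOCIO_INDICATORS:
                vals[ind] = float(srow[ind])
            for name in beta:
                raw[name].append(vals[name])

        # z-score against the analysis window (ddof=0), matching the fitter
        amask = np.array([y >= a0 for y in seasons])
        z = {}
        for name in beta:
            arr = np.asarray(raw[name], dtype=float)
            mean = arr[amask].mean()
            sd = arr[amask].std()
            if sd == 0:
                raise ConfigurationError(
                    f"predictor {name!r} has zero variance in region {region}; "
                    "cannot standardize the generative linear predictor")
            z[name] = (arr - mean) / sd

        eta = np.full(len(seasons), cfg.beta0, dtype=float)
        for name, b in beta.items():
            eta += b * z[name]
        mu = np.exp(eta)
        draws = rng.poisson(mu)
        for k, y in enumerate(seasons):
            d = int(draws[k])
            if cfg.cap_deaths_at_herd:
                d = min(d, int(np.floor(pop_pre_su[y])))
            prow = census_idx.loc[(region, y - 1)]
            alloc = _allocate_deaths(d, {sp: float(prow[sp]) for sp in SPECIES})
            deaths_by_species[(region, y)] = alloc
            if y >= a0:
                truth_rows.append({
                    "region": region, "year": y,
                    **{f"z_{n}": z[n][k] for n in beta},
                    "mu": mu[k], "deaths": d,
                })

        for y in analysis:
            d = sum(SU_RATES[sp] * deaths_by_species[(region, y)][sp]
                    for sp in SPECIES)
            d_prev = sum(SU_RATES[sp] * deaths_by_species[(region, y - 1)][sp]
                         for sp in SPECIES)
            mort_rows.append({
                "region": region, "year": y,
                "deaths_su": d,
                "pop_pre_su": pop_pre_su[y],
                "rel_mortality_pct": indices.relative_mortality(d, pop_pre_su[y]),
                "loss_pre_su": d_prev,
            })

    # write drawn deaths into the census table (season label = census year)
    for (region, y), alloc in deaths_by_species.items():
        mask = (census["region"] == region) & (census["year"] == y)
        for sp in SPECIES:
            census.loc[mask, f"deaths_{sp}"] = alloc[sp]

    return SimulatedPanel(
        climate=climate,
        census=census,
        socio=socio,
        mortality=pd.DataFrame(mort_rows),
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )
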