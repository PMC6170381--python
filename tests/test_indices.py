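"""Indicator construction: sheep units, anomalies, composites, panels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dzudrisk import (
    HAY_FORAGE_COEFFS, SU_RATES, build_risk_panel, drought_index,
    hay_forage_index, relative_mortality, snow_hazard, to_sheep_units,
    winter_temp_anomaly,
)
from dzudrisk.exceptions import DataValidationError, PanelError
from dzudrisk.indices import FEED_COMPONENTS

from conftest import make_flat_climate

herds = st.fixed_dictionaries(
    {sp: st.integers(min_value=0, max_value=10**6) for sp in SU_RATES})


class TestSheepUnits:
    @pytest.mark.parametrize("species,expected", [
        ("camels", 5.0), ("horses", 7.0), ("cattle", 6.0),
        ("sheep", 1.0), ("goats", 0.9),
    ])
    def test_unit_census_coefficients(self, species, expected):
        assert to_sheep_units({species: 1}) == expected

    def test_scaling_and_empty_herd(self):
        assert to_sheep_units({sp: 0 for sp in SU_RATES}) == 0.0
        assert to_sheep_units({"goats": 10}) == pytest.approx(9.0)

    @settings(max_examples=50, derandomize=True)
    @given(a=herds, b=herds)
    def test_linearity(self, a, b):
        combined = {sp: a[sp] + b[sp] for sp in SU_RATES}
        assert to_sheep_units(combined) == pytest.approx(
            to_sheep_units(a) + to_sheep_units(b))

    def test_errors(self):
        with pytest.raises(DataValidationError, match="unknown species"):
            to_sheep_units({"yaks": 3})
        with pytest.raises(DataValidationError, match="negative"):
            to_sheep_units({"sheep": -1})


class TestRelativeMortality:
    @pytest.mark.parametrize("deaths,total,expected", [
        (10.0, 100.0, 10.0),
        (0.0, 50.0, 0.0),
        (23.4, 100.0, 23.4),
    ])
    def test_ratio(self, deaths, total, expected):
        assert relative_mortality(deaths, total) == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(DataValidationError, match="January-1"):
            relative_mortality(1.0, 0.0)


class TestHayForage:
    @pytest.mark.parametrize("component,coef", list(HAY_FORAGE_COEFFS.items()))
    def test_unit_component_coefficients(self, component, coef):
        assert hay_forage_index({component: 1.0}) == pytest.approx(coef)

    def test_mixture(self):
        # 10 hay + 10 straw by the printed coefficients
        assert hay_forage_index({"hay": 10, "straw": 10}) == pytest.approx(7.0)

    def test_unknown_component(self):
        with pytest.raises(DataValidationError, match="valid"):
            hay_forage_index({"lichen": 1.0})


class TestDroughtIndex:
    def test_climatology_is_zero_anomaly(self):
        climate = make_flat_climate()
        assert drought_index(climate, "A", 2000) == pytest.approx(0.0)

    def test_proportionality(self):
        climate = make_flat_climate()
        frame = climate.data.copy()
        sel = (frame.year == 2011) & frame.month.isin([6, 7, 8])
        frame.loc[sel, "precip_mm"] *= 1.5
        bumped = type(climate)(frame, baseline=climate.baseline)
        assert drought_index(bumped, "A", 2011) == pytest.approx(50.0)

    def test_brute_force_oracle(self, small_sim):
        climate = small_sim.climate
        data = climate.data
        for region in ("R01", "R03"):
            sub = data[(data.region == region) & data.month.isin([6, 7, 8])]
            sums = sub.groupby("year")["precip_mm"].sum()
            b0, b1 = climate.baseline
            baseline_mean = sums.loc[b0:b1].mean()
            for year in (1998, 2005, 2013):
                expected = 100.0 * (sums.loc[year] - baseline_mean) / baseline_mean
                assert drought_index(climate, region, year) == pytest.approx(
                    expected, abs=1e-9)

    def test_missing_month(self):
        climate = make_flat_climate()
        frame = climate.data[~((climate.data.year == 2012)
                               & (climate.data.month == 7))]
        broken = type(climate)(frame, baseline=climate.baseline)
        with pytest.raises(DataValidationError, match=r"\(2012, 7\)"):
            drought_index(broken, "A", 2012)


class TestWinterTempAnomaly:
    def test_climatology_is_zero(self):
        assert winter_temp_anomaly(make_flat_climate(), "A", 2000) == \
            pytest.approx(0.0)

    def test_uniform_shift(self):
        climate = make_flat_climate()
        frame = climate.data.copy()
        cold = ((frame.year == 2010) & frame.month.isin([11, 12])) | \
               ((frame.year == 2011) & frame.month.isin([1, 2]))
        frame.loc[cold, "tmean_c"] -= 2.0
        shifted = type(climate)(frame, baseline=climate.baseline)
        assert winter_temp_anomaly(shifted, "A", 2011) == pytest.approx(-2.0)

    def test_brute_force_oracle(self, small_sim):
        climate = small_sim.climate
        data = climate.data.set_index(["region", "year", "month"])

        def composite(region, y):
            return np.mean([
                data.loc[(region, y - 1, 11), "tmean_c"],
                data.loc[(region, y - 1, 12), "tmean_c"],
                data.loc[(region, y, 1), "tmean_c"],
                data.loc[(region, y, 2), "tmean_c"],
            ])

        b0, b1 = climate.baseline
        for region in ("R01", "R02"):
            base = np.mean([composite(region, y) for y in range(b0, b1 + 1)])
            for year in (2001, 2010):
                assert winter_temp_anomaly(climate, region, year) == \
                    pytest.approx(composite(region, year) - base, abs=1e-9)


class TestSnowHazard:
    def test_january_window_identity(self):
        climate = make_flat_climate()
        frame = climate.data.copy()
        frame.loc[(frame.year == 2005) & (frame.month == 1),
                  "snowdepth_cm"] = 25.0
        c = type(climate)(frame, baseline=climate.baseline)
        assert snow_hazard(c, "A", 2005, window="january") == 25.0

    def test_nov_mar_maximum(self):
        climate = make_flat_climate(snow_by_month=np.zeros(12))
        frame = climate.data.copy()
        for (year, month), depth in {(2004, 11): 5, (2004, 12): 10,
                                     (2005, 1): 20, (2005, 2): 15,
                                     (2005, 3): 5}.items():
            frame.loc[(frame.year == year) & (frame.month == month),
                      "snowdepth_cm"] = depth
        c = type(climate)(frame, baseline=climate.baseline)
        assert snow_hazard(c, "A", 2005, window="nov-mar") == 20.0

    def test_anomaly_form_brute_force(self, small_sim):
        climate = small_sim.climate
        data = climate.data.set_index(["region", "year", "month"])
        b0, b1 = climate.baseline
        region = "R02"
        jan = [data.loc[(region, y, 1), "snowdepth_cm"]
               for y in range(b0, b1 + 1)]
        expected = data.loc[(region, 2010, 1), "snowdepth_cm"] - np.mean(jan)
        assert snow_hazard(climate, region, 2010, anomaly=True) == \
            pytest.approx(expected, abs=1e-9)

    def test_unknown_window(self):
        with pytest.raises(DataValidationError, match="valid"):
            snow_hazard(make_flat_climate(), "A", 2005, window="summer")


class TestBuildRiskPanel:
    def test_round_trip_to_generative_truth(self, small_sim, small_panels):
        """Rebuilt predictors match the generator's retained truth exactly."""
        from dzudrisk import MortalityModel
        for region, panel in small_panels.items():
            truth = small_sim.truth[small_sim.truth.region == region] \
                .set_index("year")
            model = MortalityModel.from_panel(panel)
            for j, name in enumerate(model.predictor_names):
                np.testing.assert_allclose(
                    model._Z[:, j], truth[f"z_{name}"].to_numpy(), atol=1e-9)
            assert (panel.data["deaths"].to_numpy()
                    == truth["deaths"].to_numpy()).all()

    def test_missing_month_drops_row(self, small_sim, caplog):
        climate = small_sim.climate
        frame = climate.data[~((climate.data.region == "R01")
                               & (climate.data.year == 2007)
                               & (climate.data.month == 2))]
        broken = type(climate)(frame, baseline=climate.baseline)
        panel = build_risk_panel(broken, small_sim.census, small_sim.socio,
                                 "R01")
        assert 2007 not in panel.data.index
        assert any(year == 2007 for year, _ in panel.dropped)

    def test_rounding_rule(self, small_panels):
        data = small_panels["R01"].data
        np.testing.assert_array_equal(
            data["deaths"].to_numpy(),
            np.rint(data["deaths_su"].to_numpy()).astype(int))

    def test_idempotent_and_deterministic(self, small_sim):
        a = build_risk_panel(small_sim.climate, small_sim.census,
                             small_sim.socio, "R02")
        b = build_risk_panel(small_sim.climate, small_sim.census,
                             small_sim.socio, "R02")
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_too_few_rows(self, small_sim):
        with pytest.raises(PanelError, match="need >=3"):
            build_risk_panel(small_sim.climate, small_sim.census,
                             small_sim.socio, "R01", years=(2000, 2001))
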