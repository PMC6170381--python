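"""Hotspot classification, national aggregation and the pipeline."""

import json

import numpy as np
import pytest

from dzudrisk import (
    SimulationConfig, aggregate_national, classify_hotspots, run_pipeline,
)
from dzudrisk.exceptions import DataValidationError
from dzudrisk.report import RegionRiskSummary


def _summary(region, share, r2=90.0, hazard=45.0, pop=20.0, coping=25.0,
             q2=0.95):
    return RegionRiskSummary(
        region=region, death_share_pct=share, r2_pct=r2, hazard_pct=hazard,
        pop_pre_pct=pop, coping_pct=coping, factor_pct={}, q2=q2)


class TestHotspots:
    def test_threshold_inclusive(self):
        shares = [8.0, 5.1, 4.9] + [2.0] * 41
        summaries = [_summary(f"R{i}", s) for i, s in enumerate(shares)]
        flagged = classify_hotspots(summaries)
        assert [s.hotspot for s in flagged[:3]] == [True, True, False]
        assert not any(s.hotspot for s in flagged[3:])

    def test_single_region_degenerate(self):
        (s,) = classify_hotspots([_summary("only", 100.0)])
        assert s.hotspot

    def test_uniform_22_regions_none_flagged(self):
        summaries = [_summary(f"R{i}", 100.0 / 22) for i in range(22)]
        assert not any(s.hotspot for s in classify_hotspots(summaries))

    def test_inconsistent_shares_rejected(self):
        with pytest.raises(DataValidationError, match="100"):
            classify_hotspots([_summary("a", 60.0), _summary("b", 20.0)])


class TestAggregateNational:
    def test_single_region_identity(self):
        s = _summary("a", 100.0, r2=88.0, hazard=40.0, pop=18.0, coping=30.0)
        nat = aggregate_national([s])
        assert nat["r2_pct"] == pytest.approx(88.0)
        assert nat["hazard_pct"] == pytest.approx(40.0)
        assert nat["vulnerability_pct"] == pytest.approx(48.0)

    def test_equal_weights_mean(self):
        a = _summary("a", 50.0, hazard=40.0)
        b = _summary("b", 50.0, hazard=50.0)
        assert aggregate_national([a, b])["hazard_pct"] == pytest.approx(45.0)

    def test_weighted_vs_unweighted_hand_recompute(self):
        shares = [40.0, 25.0, 15.0, 12.0, 8.0]
        hazards = [50.0, 42.0, 38.0, 61.0, 47.0]
        summaries = [_summary(f"R{i}", s, hazard=h)
                     for i, (s, h) in enumerate(zip(shares, hazards))]
        w = np.array(shares) / 100.0
        expected_w = float(np.dot(w, hazards))
        expected_u = float(np.mean(hazards))
        assert aggregate_national(summaries, "death_share")["hazard_pct"] == \
            pytest.approx(expected_w)
        assert aggregate_national(summaries, "unweighted")["hazard_pct"] == \
            pytest.approx(expected_u)

    def test_blocks_sum_to_r2(self):
        summaries = [_summary("a", 70.0), _summary("b", 30.0, r2=90.0,
                                                   hazard=50.0, pop=15.0,
                                                   coping=25.0)]
        nat = aggregate_national(summaries)
        assert nat["hazard_pct"] + nat["vulnerability_pct"] == \
            pytest.approx(nat["r2_pct"])

    def test_empty_input(self):
        with pytest.raises(DataValidationError, match="no region"):
            aggregate_national([])


@pytest.fixture(scope="module")
def pipeline_out(small_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("report")
    report = run_pipeline(small_sim, outdir=outdir)
    return report, outdir


class TestPipeline:
    def test_report_contributions_resum(self, pipeline_out):
        report, _ = pipeline_out
        for s in report.summaries:
            assert sum(s.factor_pct.values()) == pytest.approx(s.r2_pct,
                                                               abs=1e-6)
            assert s.hazard_pct + s.vulnerability_pct == pytest.approx(
                s.r2_pct, abs=1e-9)

    def test_death_shares_partition(self, pipeline_out):
        report, _ = pipeline_out
        assert sum(s.death_share_pct for s in report.summaries) == \
            pytest.approx(100.0)

    def test_selection_recovers_generative_factors(self, pipeline_out):
        """Indicators that truly drive mortality win their groups."""
        report, _ = pipeline_out
        # hay/forage carries a strong generative coefficient; shelter none
        assert report.selection.selected["winter_preparedness"] == "hay_forage"
        assert report.selection.selected["livestock"] == "pop_pre"

    def test_output_files_written(self, pipeline_out):
        _, outdir = pipeline_out
        for name in ("panel.csv", "selection.json", "fits.json",
                     "dominance.json", "cv.json", "summary.csv",
                     "report.json", "summary.txt"):
            assert (outdir / name).exists()

    def test_deterministic_report_bytes(self, tmp_path):
        cfg = SimulationConfig(n_regions=2)
        run_pipeline(cfg, outdir=tmp_path / "a", seed=3)
        run_pipeline(cfg, outdir=tmp_path / "b", seed=3)
        for name in ("report.json", "summary.csv", "summary.txt"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_hazard_only_truth_attributes_to_hazards(self):
        cfg = SimulationConfig(
            n_regions=2,
            beta={"p68": -0.5, "t112": -0.3, "sd": 0.5,
                  "pop_pre": 0.0, "hay_forage": 0.0, "h_exp": 0.0,
                  "trucks": 0.0, "l_101_200": 0.0, "gdp": 0.0})
        report = run_pipeline(cfg, seed=2)
        nat = report.national["death_share"]
        assert nat["hazard_pct"] > nat["vulnerability_pct"]

    def test_null_truth_low_r2(self):
        cfg = SimulationConfig(n_regions=2, beta={})
        report = run_pipeline(cfg, seed=6)
        nat = report.national["death_share"]
        assert nat["r2_pct"] < 60.0  # overfit noise only, no real structure

    def test_csv_input_path(self, small_sim, tmp_path):
        from dzudrisk.io import write_tables
        paths = write_tables(small_sim, tmp_path)
        report = run_pipeline({
            "climate": paths["climate"], "census": paths["census"],
            "socio": paths["socio"],
            "baseline": small_sim.config.baseline_years,
            "years": small_sim.config.analysis_years,
        })
        assert len(report.summaries) == 3
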