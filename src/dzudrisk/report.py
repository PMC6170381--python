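"""National aggregation, hotspot classification and the analysis pipeline.

Per-region dominance decompositions are expressed as percentages of
mortality explained (R²_M x 100) and aggregated to a national attribution
of hazards vs. vulnerability.  Regions holding at least a threshold share
(default 5.1 %) of national cold-season deaths are classified as mortality
hotspots.  ``run_pipeline`` orchestrates the full chain — panel
construction, indicator screening, per-region fits, dominance, LOO-CV and
the report bundle — from either a simulation config or input CSV tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .dominance import BLOCKS, DominanceDecomposition, dominance
from .exceptions import DataValidationError, PanelError
from .indices import ClimatePanel, RiskPanel, build_risk_panel
from .model import FULL_MODEL_PREDICTORS, MortalityResults, fit_pmr
from .selection import SelectionReport, correlation_screen
from .simulate import SimulatedPanel, simulate_panel
from .validation import CvResult, loo_cv

logger = logging.getLogger(__name__)

HOTSPOT_THRESHOLD_PCT = 5.1


@dataclass
class RegionRiskSummary:
    """One region's share of national mortality and its risk decomposition.

    All contribution fields are percentages of mortality explained
    (dominance weight x 100); they re-sum to ``r2_pct``.
    """

    region: str
    death_share_pct: float
    r2_pct: float
    hazard_pct: float
    pop_pre_pct: float
    coping_pct: float
    factor_pct: dict[str, float]
    q2: float
    hotspot: bool = False

    @property
    def vulnerability_pct(self) -> float:
        return self.pop_pre_pct + self.coping_pct


def summarize_region(panel: RiskPanel, dom: DominanceDecomposition,
                     cv: CvResult, death_share_pct: float) -> RegionRiskSummary:
    sums = dom.block_sums()
    return RegionRiskSummary(
        region=panel.region,
        death_share_pct=death_share_pct,
        r2_pct=100.0 * dom.full_r2,
        hazard_pct=100.0 * sums["hazards"],
        pop_pre_pct=100.0 * sums["pop_pre"],
        coping_pct=100.0 * sums["coping"],
        factor_pct={k: 100.0 * v for k, v in dom.weights.items()},
        q2=cv.q2,
    )


def classify_hotspots(summaries: Sequence[RegionRiskSummary],
                      threshold_pct: float = HOTSPOT_THRESHOLD_PCT,
                      ) -> list[RegionRiskSummary]:
    """Flag regions holding >= threshold % of national deaths.

    Death shares must partition 100 % (checked to ±0.1)."""
    total = sum(s.death_share_pct for s in summaries)
    if abs(total - 100.0) > 0.1:
        raise DataValidationError(
            f"death shares sum to {total:.3f} %, not 100 ± 0.1")
    for s in summaries:
        s.hotspot = s.death_share_pct >= threshold_pct
    return list(summaries)


def aggregate_national(summaries: Sequence[RegionRiskSummary],
                       weighting: str = "death_share") -> dict[str, float]:
    """Combine per-region decompositions into one national attribution.

    ``death_share`` (default) weights each region by its share of national
    deaths; ``unweighted`` averages regions equally.  The hazard, POP_pre
    and coping-capacity percentages sum to the aggregated full-model R²_M
    percentage by construction.
    """
    if not summaries:
        raise DataValidationError("no region summaries to aggregate")
    if weighting == "death_share":
        w = np.array([s.death_share_pct for s in summaries], dtype=float)
    elif weighting == "unweighted":
        w = np.ones(len(summaries))
    else:
        raise DataValidationError(f"unknown weighting {weighting!r}")
    if w.sum() <= 0:
        raise DataValidationError("aggregation weights sum to zero")
    w = w / w.sum()

    def avg(values) -> float:
        return float(np.dot(w, values))

    factors = sorted({f for s in summaries for f in s.factor_pct})
    out = {
        "weighting": weighting,
        "n_regions": len(summaries),
        "r2_pct": avg([s.r2_pct for s in summaries]),
        "hazard_pct": avg([s.hazard_pct for s in summaries]),
        "pop_pre_pct": avg([s.pop_pre_pct for s in summaries]),
        "coping_pct": avg([s.coping_pct for s in summaries]),
    }
    out["vulnerability_pct"] = out["pop_pre_pct"] + out["coping_pct"]
    for f in factors:
        out[f"factor_{f}_pct"] = avg([s.factor_pct.get(f, 0.0)
                                      for s in summaries])
    return out


@dataclass
class PipelineReport:
    """Everything the analysis produced, per region and nationally."""

    panels: dict[str, RiskPanel]
    selection: SelectionReport
    fits: dict[str, MortalityResults]
    decompositions: dict[str, DominanceDecomposition]
    cv: dict[str, CvResult]
    summaries: list[RegionRiskSummary]
    national: dict[str, dict]          # weighting -> aggregation
    predictors: tuple[str, ...]
    skipped_regions: dict[str, str] = field(default_factory=dict)


def build_panels(climate: ClimatePanel, census: pd.DataFrame,
                 socio: pd.DataFrame, years: tuple[int, int] = (2000, 2014),
                 **panel_kw) -> tuple[dict[str, RiskPanel], dict[str, str]]:
    """Risk panels for every region present in the census table."""
    panels, skipped = {}, {}
    for region in sorted(census["region"].unique()):
        try:
            panels[region] = build_risk_panel(
                climate, census, socio, region, years=years, **panel_kw)
        except (PanelError, DataValidationError) as exc:
            logger.warning("region %s skipped: %s", region, exc)
            skipped[region] = str(exc)
    return panels, skipped


def run_pipeline(config: SimulationConfig | SimulatedPanel | Mapping,
                 outdir=None, seed: int | None = None,
                 predictors: Sequence[str] = FULL_MODEL_PREDICTORS,
                 ) -> PipelineReport:
    """Run the full analysis and (optionally) write the report bundle.

    ``config`` may be a :class:`SimulationConfig` (a synthetic panel is
    generated), an already-simulated panel bundle, or a mapping with CSV
    paths ``{"climate": ..., "census": ..., "socio": ...}`` plus optional
    ``baseline`` and ``years`` entries.  Outputs (when ``outdir`` is given):
    panel.csv, selection.json, fits.json, dominance.json, cv.json,
    summary.csv, report.json and a plain-text summary.
    """
    years = (2000, 2014)
    if isinstance(config, SimulationConfig):
        sim = simulate_panel(config, seed=seed)
        climate, census, socio = sim.climate, sim.census, sim.socio
        years = config.analysis_years
    elif isinstance(config, SimulatedPanel):
        sim = config
        climate, census, socio = sim.climate, sim.census, sim.socio
        years = sim.config.analysis_years
    else:
        from .io import read_census, read_climate, read_socio
        baseline = tuple(config.get("baseline", (1981, 2010)))
        years = tuple(config.get("years", years))
        climate = read_climate(config["climate"], baseline=baseline)
        census = read_census(config["census"])
        socio = read_socio(config["socio"])

    panels, skipped = build_panels(climate, census, socio, years=years)
    if not panels:
        raise PanelError("no region panel could be built")
    logger.info("panel stage: %d regions built, %d skipped",
                len(panels), len(skipped))

    selection = correlation_screen(panels.values())
    logger.info("selection stage: %s", selection.selected)

    fits, decomps, cvs = {}, {}, {}
    deaths_total = {}
    for region, panel in panels.items():
        fits[region] = fit_pmr(panel, predictors)
        decomps[region] = dominance(panel, predictors)
        cvs[region] = loo_cv(panel, predictors)
        deaths_total[region] = float(panel.data["deaths_su"].sum())
    national_deaths = sum(deaths_total.values())
    logger.info("model stage: %d regions fitted", len(fits))

    summaries = [
        summarize_region(panels[r], decomps[r], cvs[r],
                         100.0 * deaths_total[r] / national_deaths)
        for r in panels
    ]
    classify_hotspots(summaries)
    national = {
        "death_share": aggregate_national(summaries, "death_share"),
        "unweighted": aggregate_national(summaries, "unweighted"),
    }

    report = PipelineReport(
        panels=panels, selection=selection, fits=fits,
        decompositions=decomps, cv=cvs, summaries=summaries,
        national=national, predictors=tuple(predictors),
        skipped_regions=skipped,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _dump_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report(report: PipelineReport, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel_frames = []
    for region, panel in report.panels.items():
        frame = panel.data.reset_index()
        frame.insert(0, "region", region)
        panel_frames.append(frame)
    pd.concat(panel_frames, ignore_index=True).to_csv(
        outdir / "panel.csv", index=False)

    _dump_json({
        "selected": report.selection.selected,
        "correlations": report.selection.table.to_dict(orient="records"),
    }, outdir / "selection.json")

    _dump_json({
        region: {
            "predictors": list(report.predictors),
            "params_std": res.params.tolist(),
            "params_raw": res.params_raw.tolist(),
            "bse_std": res.bse.tolist(),
            "llf": res.llf, "llnull": res.llnull,
            "mcfadden_r2": res.mcfadden_r2,
            "converged": res.converged, "niter": res.niter,
        } for region, res in report.fits.items()
    }, outdir / "fits.json")

    _dump_json({
        region: {
            "weights": dom.weights,
            "block_sums": dom.block_sums(),
            "sequential": dom.sequential,
            "full_r2": dom.full_r2,
            "n_subsets": dom.n_subsets,
            "n_nonconverged": dom.n_nonconverged,
        } for region, dom in report.decompositions.items()
    }, outdir / "dominance.json")

    _dump_json({
        region: {
            "q2": cv.q2, "n_folds": cv.n_folds, "n_failed": cv.n_failed,
            "acceptable": cv.acceptable,
            "folds": cv.folds.to_dict(orient="records"),
        } for region, cv in report.cv.items()
    }, outdir / "cv.json")

    summary = pd.DataFrame([{
        "region": s.region,
        "death_share_pct": round(s.death_share_pct, 1),
        "r2_pct": round(s.r2_pct, 1),
        "hazard_pct": round(s.hazard_pct, 1),
        "pop_pre_pct": round(s.pop_pre_pct, 1),
        "coping_pct": round(s.coping_pct, 1),
        "vulnerability_pct": round(s.vulnerability_pct, 1),
        "q2": round(s.q2, 3),
        "hotspot": s.hotspot,
    } for s in report.summaries])
    summary.to_csv(outdir / "summary.csv", index=False)

    _dump_json({
        "national": report.national,
        "summaries": [asdict(s) for s in report.summaries],
        "skipped_regions": report.skipped_regions,
    }, outdir / "report.json")

    nat = report.national["death_share"]
    lines = [
        "Dzud risk attribution summary",
        "=============================",
        "National aggregation weights regions by their share of national "
        "deaths (an unweighted mean is reported in report.json alongside).",
        "",
        f"Regions analysed: {len(report.summaries)} "
        f"(skipped: {len(report.skipped_regions)})",
        f"Selected factors: {', '.join(report.selection.selected_indicators)}",
        "",
        f"National mortality explained (R2_M): {nat['r2_pct']:.1f} %",
        f"  multi-hazards:        {nat['hazard_pct']:.1f} %",
        f"  vulnerability:        {nat['vulnerability_pct']:.1f} %",
        f"    livestock POP_pre:  {nat['pop_pre_pct']:.1f} %",
        f"    coping-capacity:    {nat['coping_pct']:.1f} %",
        "",
        "Hotspots (>= {:.1f} % of national deaths): {}".format(
            HOTSPOT_THRESHOLD_PCT,
            ", ".join(s.region for s in report.summaries if s.hotspot) or "none"),
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")

    return {name: outdir / name for name in (
        "panel.csv", "selection.json", "fits.json", "dominance.json",
        "cv.json", "summary.csv", "report.json", "summary.txt")}
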