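"""Correlation screening of candidate risk indicators.

Candidate indicators are organised into six groups — livestock conditions
(POP_pre, LOSS_pre), herder experience, poverty (herd-size classes),
facilities, winter preparedness and economy.  For each indicator the
Pearson correlation with cold-season deaths (SU) is computed per region and
averaged (unweighted) across regions; within each group the indicator with
the largest absolute averaged r is selected.  Applied to the national
panels this yields
the six factors of the full risk model: POP_pre, H_exp, L_101-200, trucks,
hay/forage and GDP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SelectionError
from .indices import RiskPanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndicatorGroup:
    """A named group of candidate indicators (listing order breaks ties)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise SelectionError(f"indicator group {self.name!r} is empty")


#: Fourteen candidate indicators in six groups: one livestock group and
#: five coping-capacity groups.
DEFAULT_GROUPS: tuple[IndicatorGroup, ...] = (
    IndicatorGroup("livestock", ("pop_pre", "loss_pre")),
    IndicatorGroup("herder_experience", ("h_young", "h_exp")),
    IndicatorGroup("poverty", ("l_le100", "l_101_200", "l_201_500",
                               "l_501_999", "l_ge1000")),
    IndicatorGroup("facilities", ("trucks", "tv")),
    IndicatorGroup("winter_preparedness", ("hay_forage", "shelter")),
    IndicatorGroup("economy", ("gdp",)),
)


@dataclass
class SelectionReport:
    """Averaged correlations and the per-group winners."""

    table: pd.DataFrame          # indicator, group, r_mean, n_regions, selected
    selected: dict[str, str]     # group name -> selected indicator

    @property
    def selected_indicators(self) -> list[str]:
        return list(self.selected.values())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def average_correlations(panels: Iterable[RiskPanel],
                         indicators: Sequence[str],
                         response: str = "deaths_su") -> pd.DataFrame:
    """Per-region Pearson r of each indicator with deaths, averaged.

    Regions where an indicator (or the response) has zero variance
    contribute no r for that indicator and are excluded from its average
    with a warning.
    """
    panels = list(panels)
    if not panels:
        raise SelectionError("no panels supplied")
    rows = []
    for ind in indicators:
        rs = []
        for panel in panels:
            if ind not in panel.data.columns:
                raise SelectionError(
                    f"indicator {ind!r} absent from panel {panel.region!r}")
            r = _pearson(panel.data[ind].to_numpy(dtype=float),
                         panel.data[response].to_numpy(dtype=float))
            if np.isnan(r):
                logger.warning(
                    "indicator %s has undefined r in region %s (zero "
                    "variance); excluded from the average", ind, panel.region)
                continue
            rs.append(r)
        rows.append({"indicator": ind,
                     "r_mean": float(np.mean(rs)) if rs else np.nan,
                     "n_regions": len(rs)})
    return pd.DataFrame(rows)


def select_from_correlations(r_mean: Mapping[str, float],
                             groups: Sequence[IndicatorGroup] = DEFAULT_GROUPS,
                             ) -> dict[str, str]:
    """Pick the max-|r̄| member of each group (pure function of the r̄ table).

    Ties break by group listing order; a group whose members all lack a
    usable r̄ raises.
    """
    selected = {}
    for group in groups:
        best, best_abs = None, -np.inf
        for member in group.members:
            r = r_mean.get(member, np.nan)
            if r is None or np.isnan(r):
                continue
            if abs(r) > best_abs:
                best, best_abs = member, abs(r)
        if best is None:
            raise SelectionError(
                f"group {group.name!r}: no indicator has a defined averaged r")
        selected[group.name] = best
    return selected


def correlation_screen(panels: Iterable[RiskPanel],
                       groups: Sequence[IndicatorGroup] = DEFAULT_GROUPS,
                       response: str = "deaths_su") -> SelectionReport:
    """Screen all group members against deaths and mark per-group winners."""
    panels = list(panels)
    indicators = [m for g in groups for m in g.members]
    table = average_correlations(panels, indicators, response=response)
    group_of = {m: g.name for g in groups for m in g.members}
    table["group"] = table["indicator"].map(group_of)
    r_mean = dict(zip(table["indicator"], table["r_mean"]))
    selected = select_from_correlations(r_mean, groups)
    table["selected"] = table.apply(
        lambda row: selected.get(row["group"]) == row["indicator"], axis=1)
    return SelectionReport(table=table, selected=selected)
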