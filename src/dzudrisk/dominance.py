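"""All-subsets dominance analysis of the Poisson mortality regression.

General dominance partitions the full-model McFadden R²_M across the
predictors: the weight of predictor j is the average, over subset sizes k,
of the mean R²_M increment obtained by adding j to size-k subsets that
exclude it.  The weights are non-negative up to numerical noise and sum
exactly to the full-model R²_M when every subset model converges — the
decomposition behind "x% of mortality explained by hazards vs.
vulnerability" statements.

Sequential increments follow the conventional nested build order instead
(hazards -> livestock population -> coping-capacity) and are reported
side by side: the two attributions answer slightly different questions and
coincide only for orthogonal predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .exceptions import FitError
from .indices import RiskPanel
from .model import FULL_MODEL_PREDICTORS, MortalityModel

logger = logging.getLogger(__name__)

#: Conventional predictor blocks of the risk decomposition.
BLOCKS: dict[str, tuple[str, ...]] = {
    "hazards": ("p68", "t112", "sd"),
    "pop_pre": ("pop_pre",),
    "coping": ("hay_forage", "h_exp", "trucks", "l_101_200", "gdp"),
}

MAX_PREDICTORS = 15  # 2^15 subset refits ceiling


@dataclass
class DominanceDecomposition:
    """Per-predictor general dominance weights for one region model.

    ``weights`` are shares of R²_M (sum to ``full_r2``); ``block_sums``
    aggregates them over the hazard / POP_pre / coping-capacity blocks;
    ``sequential`` holds the nested-build R²_M increments per block.
    """

    region: str | None
    predictors: tuple[str, ...]
    weights: dict[str, float]
    full_r2: float
    sequential: dict[str, float] = field(default_factory=dict)
    n_subsets: int = 0
    n_nonconverged: int = 0

    def block_sums(self, blocks: Mapping[str, Sequence[str]] = BLOCKS
                   ) -> dict[str, float]:
        out = {}
        for name, members in blocks.items():
            out[name] = sum(self.weights.get(m, 0.0) for m in members)
        return out

    @property
    def vulnerability(self) -> float:
        """POP_pre plus coping-capacity weight (the non-hazard share)."""
        sums = self.block_sums()
        return sums["pop_pre"] + sums["coping"]


def _subset_r2(panel: RiskPanel, predictors: Sequence[str]
               ) -> tuple[dict[frozenset, float], int]:
    """McFadden R²_M for every subset of `predictors` (2^p fits).

    Non-converged subset fits are excluded (returned count) rather than
    imputed.
    """
    y = panel.data["deaths"].to_numpy()
    Xall = panel.data[list(predictors)].to_numpy()
    p = len(predictors)
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    n_bad = 0
    for k in range(1, p + 1):
        for combo in combinations(range(p), k):
            names = tuple(predictors[j] for j in combo)
            try:
                res = MortalityModel(
                    y, Xall[:, combo], names, region=panel.region).fit()
            except FitError:
                n_bad += 1
                continue
            if not res.converged:
                n_bad += 1
                continue
            r2[frozenset(names)] = res.mcfadden_r2
    return r2, n_bad


def dominance(panel: RiskPanel,
              predictors: Sequence[str] = FULL_MODEL_PREDICTORS,
              sequential_blocks: Mapping[str, Sequence[str]] | None = BLOCKS,
              ) -> DominanceDecomposition:
    """General dominance decomposition of the full-model R²_M.

    Fits all ``2^p`` subset models; predictors beyond 15 are refused.  If
    more than 20 % of subset fits fail to converge the decomposition is
    considered unreliable and an error is raised.
    """
    predictors = tuple(predictors)
    p = len(predictors)
    if p > MAX_PREDICTORS:
        raise FitError(f"{p} predictors exceed the {MAX_PREDICTORS}-predictor "
                       "all-subsets ceiling")
    r2, n_bad = _subset_r2(panel, predictors)
    n_total = 2 ** p
    if n_bad:
        logger.warning("region %s: %d/%d subset fits non-converged",
                       panel.region, n_bad, n_total)
    if n_bad > 0.2 * n_total:
        raise FitError(
            f"{n_bad}/{n_total} subset fits non-converged; dominance "
            "decomposition unreliable")
    full = frozenset(predictors)
    if full not in r2:
        raise FitError("full model did not converge")

    import warnings
    weights = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n refits warn once already
        for name in predictors:
            others = [q for q in predictors if q != name]
            level_means = []
            for k in range(p):
                incs = []
                for combo in combinations(others, k):
                    s = frozenset(combo)
                    s_j = s | {name}
                    if s in r2 and s_j in r2:
                        incs.append(r2[s_j] - r2[s])
                if incs:
                    level_means.append(float(np.mean(incs)))
            weights[name] = float(np.mean(level_means))

    seq = {}
    if sequential_blocks is not None:
        blocks = {nm: [q for q in members if q in predictors]
                  for nm, members in sequential_blocks.items()}
        blocks = {nm: mem for nm, mem in blocks.items() if mem}
        seq = sequential_increments(panel, blocks)

    return DominanceDecomposition(
        region=panel.region,
        predictors=predictors,
        weights=weights,
        full_r2=r2[full],
        sequential=seq,
        n_subsets=n_total,
        n_nonconverged=n_bad,
    )


def sequential_increments(panel: RiskPanel,
                          ordered_blocks: Mapping[str, Sequence[str]],
                          ) -> dict[str, float]:
    """R²_M increments along a nested build order of predictor blocks.

    Blocks are added cumulatively (e.g. hazards, then POP_pre, then
    coping-capacity); the per-block deltas sum to the full-model R²_M.
    A non-converged nested fit raises, naming the failing block.
    """
    import warnings
    increments: dict[str, float] = {}
    current: list[str] = []
    prev_r2 = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, members in ordered_blocks.items():
            current = current + list(members)
            res = MortalityModel.from_panel(panel, tuple(current)).fit()
            if not res.converged:
                raise FitError(f"nested fit for block {name!r} did not converge")
            increments[name] = res.mcfadden_r2 - prev_r2
            prev_r2 = res.mcfadden_r2
    return increments
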