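"""Leave-one-out cross-validation of the full mortality model.

Each cold-season row is held out in turn, the model refitted on the
remaining rows, and the held-out deaths predicted on the natural count
scale.  Predictive ability is summarised by

    Q2 = 1 - sum_i (yhat_i - y_i)^2 / sum_i (y_i - ybar)^2

with ``ybar`` the mean observed deaths over *all* n rows.  Q² is 1 for
perfect prediction, 0 for a predictor no better than the overall mean, and
may be negative; values >= 0.4 are conventionally considered acceptable for
biological models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CrossValidationError, FitError
from .indices import RiskPanel
from .model import FULL_MODEL_PREDICTORS, MortalityModel

ACCEPTABLE_Q2 = 0.4


@dataclass
class CvResult:
    """Per-fold held-out predictions and the Q² statistic."""

    region: str | None
    folds: pd.DataFrame          # year, observed, predicted, converged
    q2: float
    n_folds: int
    n_failed: int

    @property
    def acceptable(self) -> bool:
        return self.q2 >= ACCEPTABLE_Q2


def q_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Prediction-error statistic against the all-sample mean baseline."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise CrossValidationError("observed and predicted lengths differ")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0:
        raise CrossValidationError("observed deaths are constant; Q2 undefined")
    return 1.0 - float(np.sum((yhat - y) ** 2)) / denom


def loo_cv(panel: RiskPanel,
           predictors: Sequence[str] = FULL_MODEL_PREDICTORS,
           max_failed: int = 1) -> CvResult:
    """Leave-one-out cross-validation of the PMR on one region panel.

    Performs exactly n held-out refits (n = usable panel rows).  A fold
    whose refit does not converge is recorded as failed; with more than
    ``max_failed`` failures Q² is not reported and an error is raised.
    """
    data = panel.data
    n = len(data)
    if n < 4:
        raise CrossValidationError(
            f"region {panel.region!r}: {n} rows; need >=4 for LOO-CV")
    y = data["deaths"].to_numpy(dtype=float)
    X = data[list(predictors)].to_numpy(dtype=float)
    years = data.index.to_numpy()

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n-1 rows vs p predictors warns
        for i in range(n):
            keep = np.arange(n) != i
            try:
                res = MortalityModel(
                    y[keep], X[keep], predictors, region=panel.region).fit()
                ok = res.converged
                pred = float(res.predict(X[i:i + 1])[0]) if ok else np.nan
            except FitError:
                ok, pred = False, np.nan
            rows.append({"year": years[i], "observed": y[i],
                         "predicted": pred, "converged": ok})
    folds = pd.DataFrame(rows)
    n_failed = int((~folds["converged"]).sum())
    if n_failed > max_failed:
        raise CrossValidationError(
            f"region {panel.region!r}: {n_failed}/{n} LOO folds failed; "
            "Q2 not reported")
    good = folds["converged"].to_numpy()
    q2 = q_squared(folds.loc[good, "observed"].to_numpy(),
                   folds.loc[good, "predicted"].to_numpy())
    return CvResult(region=panel.region, folds=folds, q2=q2,
                    n_folds=n, n_failed=n_failed)
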