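"""Poisson multi-regression (PMR) of cold-season livestock deaths.

The mortality model is a log-linear Poisson regression,

    y_i ~ Poisson(mu_i),    mu_i = exp(beta_0 + sum_j beta_j x_ij),

fitted by maximum likelihood with Newton/IRLS iterations on internally
z-scored predictors (raw predictor scales span six orders of magnitude, so
standardization is needed for conditioning; estimates are reported on both
scales).  Goodness of fit uses McFadden's pseudo-R²,

    R2_M = 1 - llf / llnull,

with the intercept-only model on the same rows as null.  No exposure offset
is used by default: the model explains raw death counts with the preceding
herd size as an ordinary covariate; an optional ``log(POP_pre)`` offset is
available.

Standard errors come from the observed information matrix and serve as
diagnostics (e.g. simulation coverage checks); overdispersion is not
modelled, but a Pearson dispersion statistic is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .exceptions import FitError, PanelError
from .indices import RiskPanel

#: The nine factors of the full risk model, in the conventional build order
#: (hazards, then livestock population, then coping-capacity).
FULL_MODEL_PREDICTORS: tuple[str, ...] = (
    "p68", "t112", "sd", "pop_pre",
    "hay_forage", "h_exp", "trucks", "l_101_200", "gdp",
)

_ETA_MAX = 500.0  # exp overflow guard on the linear predictor


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood ``sum_i (y_i ln mu_i - mu_i - ln y_i!)``.

    Uses the log-gamma formulation, numerically stable for counts up to
    ~1e8.  ``y`` must hold non-negative integers (count rounding is the
    panel builder's job) and ``mu`` must be strictly positive.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise FitError("y and mu must have equal length")
    if np.any(y < 0) or np.any(y != np.rint(y)):
        raise FitError("y must contain non-negative integers")
    if np.any(mu <= 0):
        raise FitError("mu must be strictly positive")
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


@dataclass
class MortalityResults:
    """Fitted PMR: estimates, uncertainties and diagnostics.

    Coefficients are reported both on the internal standardized scale
    (``params``, intercept first) and back-transformed to the raw predictor
    scale (``params_raw``).
    """

    model: "MortalityModel"
    params: np.ndarray
    params_raw: np.ndarray
    bse: np.ndarray
    bse_raw: np.ndarray
    llf: float
    llnull: float
    niter: int
    converged: bool
    cond_number: float
    fittedvalues: np.ndarray = field(repr=False)

    @property
    def mcfadden_r2(self) -> float:
        """McFadden pseudo-R²: 1 - llf/llnull (0 for the null model)."""
        if self.llnull == 0.0:
            raise FitError("degenerate null log-likelihood (llnull = 0)")
        r2 = 1.0 - self.llf / self.llnull
        return 0.0 if abs(r2) < 1e-12 else r2

    @property
    def dispersion(self) -> float:
        """Pearson chi-square / residual d.f. (diagnostic only)."""
        y = self.model.endog
        mu = self.fittedvalues
        dof = max(len(y) - len(self.params), 1)
        return float(np.sum((y - mu) ** 2 / mu) / dof)

    def predict(self, exog_raw: np.ndarray) -> np.ndarray:
        """Expected deaths for raw-scale predictor rows (n x p)."""
        X = np.atleast_2d(np.asarray(exog_raw, dtype=float))
        eta = self.params_raw[0] + X @ self.params_raw[1:]
        if self.model.offset is not None:
            raise FitError("predict() with an offset model requires "
                           "MortalityModel.predict_with_offset")
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    def summary(self) -> str:
        names = ["intercept"] + list(self.model.predictor_names)
        lines = [
            f"Poisson mortality regression — region "
            f"{self.model.region or '(unnamed)'}",
            f"  n obs: {len(self.model.endog)}   predictors: "
            f"{len(self.model.predictor_names)}",
            f"  log-likelihood: {self.llf:.4f}   null: {self.llnull:.4f}",
            f"  McFadden R2_M: {self.mcfadden_r2:.4f}   "
            f"dispersion: {self.dispersion:.3f}",
            f"  converged: {self.converged} in {self.niter} iterations   "
            f"cond(X'WX): {self.cond_number:.3g}",
            "",
            f"  {'term':<12}{'coef(std)':>12}{'se(std)':>10}"
            f"{'coef(raw)':>14}{'se(raw)':>12}",
        ]
        for i, nm in enumerate(names):
            lines.append(
                f"  {nm:<12}{self.params[i]:>12.4f}{self.bse[i]:>10.4f}"
                f"{self.params_raw[i]:>14.6g}{self.bse_raw[i]:>12.3g}")
        return "\n".join(lines)


class MortalityModel:
    """Poisson log-linear model of cold-season deaths for one region.

    Parameters
    ----------
    endog :
        Integer death counts (SU totals rounded by the panel builder).
    exog :
        Raw-scale predictor matrix, one column per name in
        ``predictor_names`` (no intercept column; added internally).
    predictor_names :
        Column labels for ``exog``.
    offset :
        Optional per-row additive offset on the log scale (e.g.
        ``log(POP_pre)`` for a rate model); off by default.
    """

    def __init__(self, endog, exog, predictor_names, offset=None,
                 region: str | None = None, years=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.size == 0:
            self.exog = np.empty((len(self.endog), 0))
        if self.exog.shape[0] != len(self.endog):
            raise FitError("endog and exog row counts differ")
        self.predictor_names = list(predictor_names)
        if self.exog.shape[1] != len(self.predictor_names):
            raise FitError("predictor_names does not match exog columns")
        self.offset = None if offset is None else np.asarray(offset, float)
        self.region = region
        self.years = None if years is None else np.asarray(years)
        if np.any(self.endog < 0) or np.any(self.endog != np.rint(self.endog)):
            raise FitError("death counts must be non-negative integers")

        n, p = self.exog.shape
        if n < p + 2:
            import warnings
            warnings.warn(
                f"only {n} observations for {p} predictors; estimates will "
                "be weakly determined", stacklevel=2)

        # internal standardization (ddof=0); constant columns are an error
        self._means = self.exog.mean(axis=0) if p else np.empty(0)
        self._sds = self.exog.std(axis=0) if p else np.empty(0)
        zero = [self.predictor_names[j] for j in np.flatnonzero(self._sds == 0)]
        if zero:
            raise FitError(f"constant predictor column(s): {zero}")
        self._Z = ((self.exog - self._means) / self._sds) if p \
            else np.empty((n, 0))
        X = np.column_stack([np.ones(n), self._Z])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            corr = np.corrcoef(self._Z, rowvar=False)
            pairs = [
                (self.predictor_names[a], self.predictor_names[b])
                for a in range(p) for b in range(a + 1, p)
                if abs(corr[a, b]) > 1 - 1e-10
            ]
            raise FitError(
                f"rank-deficient design; collinear columns: {pairs or zero}")
        self._X = X

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_panel(cls, panel: RiskPanel, predictors=FULL_MODEL_PREDICTORS,
                   use_offset: bool = False) -> "MortalityModel":
        missing = [pvar for pvar in predictors if pvar not in panel.data.columns]
        if missing:
            raise PanelError(f"panel for region {panel.region!r} lacks "
                             f"predictors {missing}")
        offset = np.log(panel.data["pop_pre"].to_numpy()) if use_offset else None
        return cls(
            endog=panel.data["deaths"].to_numpy(),
            exog=panel.data[list(predictors)].to_numpy(),
            predictor_names=predictors,
            offset=offset,
            region=panel.region,
            years=panel.data.index.to_numpy(),
        )

    @classmethod
    def from_dataframe(cls, frame, response: str = "deaths",
                       predictors=FULL_MODEL_PREDICTORS,
                       region: str | None = None) -> "MortalityModel":
        return cls(frame[response].to_numpy(),
                   frame[list(predictors)].to_numpy(),
                   predictors, region=region)

    # -- likelihood machinery ----------------------------------------------

    def _eta(self, beta: np.ndarray) -> np.ndarray:
        eta = self._X @ beta
        if self.offset is not None:
            eta = eta + self.offset
        return np.clip(eta, -_ETA_MAX, _ETA_MAX)

    def loglike(self, beta: np.ndarray) -> float:
        return poisson_loglik(self.endog, np.exp(self._eta(beta)))

    def _null_loglik(self) -> float:
        ybar = self.endog.mean()
        if self.offset is None:
            if ybar <= 0:
                raise FitError("all-zero death counts: null model degenerate")
            mu = np.full_like(self.endog, ybar)
        else:
            # intercept-only MLE with offset: exp(b0) = sum y / sum exp(offset)
            w = np.exp(self.offset)
            mu = w * (self.endog.sum() / w.sum())
            if np.any(mu <= 0):
                raise FitError("degenerate null model with offset")
        return poisson_loglik(self.endog, mu)

    def fit(self, tol: float = 1e-10, maxiter: int = 100) -> MortalityResults:
        """Maximum likelihood via Newton/IRLS with step-halving.

        The log-likelihood is non-decreasing across iterations; convergence
        is declared when its relative change falls below ``tol``.  On
        divergence the results carry ``converged=False`` (no silent answer).
        """
        y = self.endog
        n, pfull = self._X.shape
        if y.sum() <= 0:
            raise FitError("all-zero death counts: Poisson MLE degenerate")
        beta = np.zeros(pfull)
        beta[0] = math.log(y.mean()) - (np.mean(self.offset)
                                        if self.offset is not None else 0.0)
        ll = self.loglike(beta)
        converged = False
        H = np.eye(pfull)
        it = 0
        for it in range(1, maxiter + 1):
            mu = np.exp(self._eta(beta))
            grad = self._X.T @ (y - mu)
            H = self._X.T @ (mu[:, None] * self._X)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step, *_ = np.linalg.lstsq(H, grad, rcond=None)
            # step-halving keeps the log-likelihood monotone
            new_ll, scale = -np.inf, 1.0
            for _ in range(50):
                cand = beta + scale * step
                new_ll = self.loglike(cand)
                if new_ll >= ll - 1e-13:
                    break
                scale *= 0.5
            else:
                break
            beta, prev_ll, ll = cand, ll, new_ll
            if abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
                converged = True
                break

        mu = np.exp(self._eta(beta))
        H = self._X.T @ (mu[:, None] * self._X)
        try:
            cov = np.linalg.inv(H)
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            cov = np.full((pfull, pfull), np.nan)
            bse = np.full(pfull, np.nan)
        cond = float(np.linalg.cond(H))

        # back-transform: beta_raw_j = beta_j / sd_j;
        # intercept_raw = b0 - sum_j beta_j mean_j / sd_j
        T = np.eye(pfull)
        for j in range(1, pfull):
            sd, mean = self._sds[j - 1], self._means[j - 1]
            T[j, j] = 1.0 / sd
            T[0, j] = -mean / sd
        params_raw = T @ beta
        cov_raw = T @ cov @ T.T
        bse_raw = np.sqrt(np.maximum(np.diag(cov_raw), 0.0))

        return MortalityResults(
            model=self,
            params=beta,
            params_raw=params_raw,
            bse=bse,
            bse_raw=bse_raw,
            llf=ll,
            llnull=self._null_loglik(),
            niter=it,
            converged=converged,
            cond_number=cond,
            fittedvalues=mu,
        )


def fit_pmr(panel: RiskPanel, predictors=FULL_MODEL_PREDICTORS,
            use_offset: bool = False, **fit_kw) -> MortalityResults:
    """Convenience wrapper: build and fit the PMR for one region panel."""
    return MortalityModel.from_panel(panel, predictors,
                                     use_offset=use_offset).fit(**fit_kw)


def mcfadden_r2(results: MortalityResults) -> float:
    """McFadden pseudo-R² of a fitted model (1 - llf/llnull)."""
    if not results.converged:
        raise FitError("fit did not converge; R2_M not reliable")
    return results.mcfadden_r2
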