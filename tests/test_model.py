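"""Poisson regression fitting: likelihood, MLE, McFadden R², diagnostics."""

import math

import numpy as np
import pytest

from dzudrisk import MortalityModel, fit_pmr, poisson_loglik
from dzudrisk.exceptions import FitError


class TestPoissonLoglik:
    def test_closed_forms(self):
        assert poisson_loglik([0], [1.0]) == pytest.approx(-1.0)
        assert poisson_loglik([2], [2.0]) == pytest.approx(math.log(2) - 2)

    def test_exact_factorial_oracle(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 20, size=12)
        mu = rng.uniform(0.5, 15.0, size=12)
        expected = sum(
            yi * math.log(m) - m - math.log(math.factorial(int(yi)))
            for yi, m in zip(y, mu))
        assert poisson_loglik(y, mu) == pytest.approx(expected, abs=1e-10)

    def test_large_counts_stable(self):
        y = np.array([10**8])
        mu = np.array([1e8])
        assert np.isfinite(poisson_loglik(y, mu))

    def test_errors(self):
        with pytest.raises(FitError, match="integer"):
            poisson_loglik([1.5], [1.0])
        with pytest.raises(FitError, match="positive"):
            poisson_loglik([1], [0.0])
        with pytest.raises(FitError, match="non-negative"):
            poisson_loglik([-1], [1.0])


def _toy(seed=0, n=8, beta=(1.5, 0.6, -0.4)):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta) - 1))
    mu = np.exp(beta[0] + X @ np.array(beta[1:]))
    y = rng.poisson(mu)
    return y, X


class TestFit:
    def test_intercept_only_closed_form(self):
        res = MortalityModel([2, 2, 2], np.empty((3, 0)), []).fit()
        assert res.params[0] == pytest.approx(math.log(2))
        np.testing.assert_allclose(res.fittedvalues, 2.0)
        assert res.mcfadden_r2 == 0.0

    def test_score_equation_for_intercept(self):
        y, X = _toy(seed=3)
        res = MortalityModel(y, X, ["a", "b"]).fit()
        assert res.converged
        assert res.fittedvalues.sum() == pytest.approx(y.sum(), rel=1e-8)

    def test_grid_search_mle_oracle(self):
        """The IRLS optimum matches a dense grid search of the likelihood."""
        y, X = _toy(seed=1)
        model = MortalityModel(y, X, ["a", "b"])
        res = model.fit()
        Z = np.column_stack([np.ones(len(y)), model._Z])
        step = 0.01
        axes = [np.arange(c - 0.25, c + 0.25 + step / 2, step)
                for c in res.params]
        grids = np.meshgrid(*axes, indexing="ij")
        B = np.stack([g.ravel() for g in grids], axis=1)
        mu = np.exp(B @ Z.T)
        from scipy.special import gammaln
        ll = (y * np.log(mu) - mu - gammaln(np.asarray(y) + 1.0)).sum(axis=1)
        best = B[np.argmax(ll)]
        np.testing.assert_allclose(res.params, best, atol=step)
        assert model.loglike(res.params) >= ll.max() - 1e-9

    def test_gradient_at_optimum(self):
        y, X = _toy(seed=5)
        model = MortalityModel(y, X, ["a", "b"])
        res = model.fit()
        mu = res.fittedvalues
        grad = np.column_stack([np.ones(len(y)), model._Z]).T @ (y - mu)
        assert np.linalg.norm(grad) < 1e-6

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        y, X = _toy(seed=8, n=30)
        model = MortalityModel(y, X, ["a", "b"])
        res = model.fit()
        Z = np.column_stack([np.ones(len(y)), model._Z])
        ref = sm.GLM(y, Z, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(res.params, ref.params, atol=1e-7)
        np.testing.assert_allclose(res.bse, ref.bse, atol=1e-7)
        assert res.llf == pytest.approx(ref.llf, abs=1e-7)

    def test_raw_scale_params_reproduce_fit(self):
        y, X = _toy(seed=2)
        res = MortalityModel(y, X, ["a", "b"]).fit()
        mu_raw = np.exp(res.params_raw[0] + X @ res.params_raw[1:])
        np.testing.assert_allclose(mu_raw, res.fittedvalues, rtol=1e-8)

    def test_single_region_recovery_within_5se(self, small_sim, small_panels):
        truth = small_sim.config.beta
        res = fit_pmr(small_panels["R02"])
        for j, name in enumerate(res.model.predictor_names):
            err = abs(res.params[j + 1] - truth[name])
            assert err < 5 * res.bse[j + 1], name

    def test_constant_predictor_rejected(self):
        y = [1, 2, 3, 4]
        X = np.column_stack([np.ones(4)])
        with pytest.raises(FitError, match="constant"):
            MortalityModel(y, X, ["const"])

    def test_collinear_design_rejected(self):
        y, X = _toy(seed=4)
        X2 = np.column_stack([X[:, 0], 2.0 * X[:, 0] + 1.0])
        with pytest.raises(FitError, match="collinear"):
            MortalityModel(y, X2, ["a", "a2"])

    def test_all_zero_deaths_degenerate(self):
        X = np.arange(5.0).reshape(-1, 1)
        with pytest.raises(FitError, match="zero"):
            MortalityModel(np.zeros(5), X, ["a"]).fit()

    def test_small_sample_warns(self):
        y, X = _toy(seed=6, n=3)
        with pytest.warns(UserWarning, match="observations"):
            MortalityModel(y, X, ["a", "b"])


class TestMcFaddenR2:
    def test_nested_monotone_and_bounded(self, small_panels):
        """R²_M grows along nested models and stays in [0, 1)."""
        panel = small_panels["R01"]
        order = ["p68", "t112", "sd", "pop_pre", "hay_forage"]
        prev = 0.0
        for k in range(1, len(order) + 1):
            r2 = fit_pmr(panel, tuple(order[:k])).mcfadden_r2
            assert 0.0 <= r2 < 1.0
            assert r2 >= prev - 1e-12
            prev = r2

    @pytest.mark.parametrize("scale,shift", [(2.0, 0.0), (0.5, 10.0),
                                             (-3.0, -7.0)])
    def test_affine_invariance(self, small_panels, scale, shift):
        panel = small_panels["R03"]
        y = panel.data["deaths"].to_numpy()
        X = panel.data[["p68", "sd"]].to_numpy()
        base = MortalityModel(y, X, ["p68", "sd"]).fit().mcfadden_r2
        Xt = X.copy()
        Xt[:, 1] = scale * Xt[:, 1] + shift
        trans = MortalityModel(y, Xt, ["p68", "sd_t"]).fit().mcfadden_r2
        assert trans == pytest.approx(base, abs=1e-9)

    def test_offset_option(self, small_panels):
        res = fit_pmr(small_panels["R01"], ("p68", "sd"), use_offset=True)
        assert res.converged
        assert 0.0 <= res.mcfadden_r2 < 1.0
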