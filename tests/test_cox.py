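"""Cox and logistic engines: analytic toys, oracle agreement, invariances."""

import numpy as np
import pytest
from scipy import stats

from sigsurv import _engine
from sigsurv.cox import (
    cox_penalized,
    cox_univariate,
    importance_s36,
    lambda_grid,
    logistic_penalized,
    select_lambda_loocv,
    standardize,
    _sorted_arrays,
)
from sigsurv.data import SurvivalOutcome
from sigsurv.simulate import generate_cohort

import _oracles
from conftest import noise_config, random_survival, signal_config


def toy3() -> SurvivalOutcome:
    return SurvivalOutcome(time=np.array([1.0, 2.0, 3.0]), event=np.array([1, 1, 1]))


class TestUnivariate:
    def test_analytic_three_subject_instance(self):
        """Score equation 1 = 2u/(2u+1) + u/(1+u) solves to beta = -ln2/2."""
        res = cox_univariate(np.array([1.0, 0.0, 1.0]), toy3())
        assert res.beta == pytest.approx(-np.log(2.0) / 2.0, abs=1e-6)
        assert res.hr == pytest.approx(np.exp(-np.log(2.0) / 2.0), abs=1e-6)

    def test_agrees_with_neldermead_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(15, 30))
            out = random_survival(rng, n)
            p = int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            fit = cox_penalized(X, out, penalty="none", lambda_=0.0)
            oracle = _oracles.cox_fit_neldermead(
                (X - X.mean(0)) / X.std(0), out.time, out.event
            )
            assert np.allclose(fit.beta_std, oracle, atol=1e-5)

    def test_null_p_values_approximately_uniform(self, rng):
        ps = []
        for _ in range(200):
            out = random_survival(rng, 100)
            x = rng.standard_normal(100)
            ps.append(cox_univariate(x, out).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_reparameterization_invariance(self, rng):
        out = random_survival(rng, 60)
        x = rng.standard_normal(60)
        r1 = cox_univariate(x, out)
        r2 = cox_univariate(2.0 * x, out)
        assert r2.beta == pytest.approx(r1.beta / 2.0, rel=1e-6)
        assert r2.p == pytest.approx(r1.p, rel=1e-6)

    def test_requires_two_events_and_variation(self):
        with pytest.raises(ValueError, match="2 events"):
            cox_univariate(
                np.array([1.0, 2.0]),
                SurvivalOutcome(np.array([1.0, 2.0]), np.array([1, 0])),
            )
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(np.ones(3), toy3())

    def test_monotone_likelihood_flagged(self):
        # perfectly separating covariate: later times, larger x
        out = toy3()
        with pytest.warns(UserWarning, match="converge"):
            res = cox_univariate(np.array([3.0, 2.0, 1.0]) * 10, out)
        assert not res.converged and np.isnan(res.hr)


class TestBreslowBaseline:
    def test_hand_summed_cumulative_hazard(self):
        """Events at t=1,2,3 with beta=0: H0 = 1/3, 5/6, 11/6."""
        fit = cox_penalized(np.zeros((3, 1)), toy3(), penalty="none")
        assert np.allclose(fit.baseline_cumhaz, [1 / 3, 5 / 6, 11 / 6], atol=1e-9)
        assert fit.baseline_survival(3.0) == pytest.approx(np.exp(-11 / 6), abs=1e-9)


class TestPenalized:
    def test_lambda_zero_matches_unpenalized(self, rng):
        out = random_survival(rng, 50)
        X = rng.standard_normal((50, 3))
        a = cox_penalized(X, out, penalty="none")
        b = cox_penalized(X, out, penalty="ridge", lambda_=0.0)
        c = cox_penalized(X, out, penalty="lasso", lambda_=0.0)
        assert np.allclose(a.beta_std, b.beta_std, atol=1e-6)
        assert np.allclose(a.beta_std, c.beta_std, atol=1e-6)

    def test_lasso_all_zero_at_lambda_max(self, rng):
        out = random_survival(rng, 60)
        X = rng.standard_normal((60, 5))
        Xstd, _, _ = standardize(X)
        _, _, Xs, XsT, delta, first, last = _sorted_arrays(out, Xstd)
        lam_max = _engine.null_score_max(Xs, XsT, delta, np.ones(60), first, last)
        fit = cox_penalized(X, out, penalty="lasso", lambda_=lam_max * 1.000001)
        assert np.all(fit.beta_std == 0.0)
        assert set(fit.excluded) == set(fit.variables)

    def test_lasso_matches_neldermead_oracle(self, rng):
        for _ in range(5):
            out = random_survival(rng, 40)
            X = rng.standard_normal((40, 2))
            lam = 1.5
            fit = cox_penalized(X, out, penalty="lasso", lambda_=lam)
            oracle = _oracles.cox_fit_neldermead(
                (X - X.mean(0)) / X.std(0), out.time, out.event, lam=lam, l1=True
            )
            assert np.allclose(fit.beta_std, oracle, atol=2e-4)

    def test_ridge_matches_neldermead_oracle(self, rng):
        for _ in range(5):
            out = random_survival(rng, 40)
            X = rng.standard_normal((40, 3))
            lam = 4.0
            fit = cox_penalized(X, out, penalty="ridge", lambda_=lam)
            oracle = _oracles.cox_fit_neldermead(
                (X - X.mean(0)) / X.std(0), out.time, out.event, lam=lam
            )
            assert np.allclose(fit.beta_std, oracle, atol=1e-5)

    def test_ridge_shrinkage_monotone_in_lambda(self, rng):
        for _ in range(20):
            out = random_survival(rng, 40)
            X = rng.standard_normal((40, 4))
            norms = [
                np.linalg.norm(cox_penalized(X, out, "ridge", lam).beta_std)
                for lam in (0.5, 2.0, 8.0, 32.0, 128.0)
            ]
            assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))
            assert norms[-1] < 0.2 * norms[0] + 1e-9

    def test_ridge_path_continuous(self, rng):
        out = random_survival(rng, 60)
        X = rng.standard_normal((60, 4))
        grid = np.logspace(2, -2, 60)
        prev = None
        for lam in grid:
            b = cox_penalized(X, out, "ridge", lam).beta_std
            if prev is not None:
                assert np.linalg.norm(b - prev) < 0.15 * (1 + np.linalg.norm(b))
            prev = b

    def test_standardization_invariance(self, rng):
        out = random_survival(rng, 50)
        X = rng.standard_normal((50, 3))
        X2 = X.copy()
        X2[:, 1] *= 7.0
        a = cox_penalized(X, out, "ridge", 3.0)
        b = cox_penalized(X2, out, "ridge", 3.0)
        assert np.allclose(a.beta_std, b.beta_std, atol=1e-8)
        assert b.beta[1] == pytest.approx(a.beta[1] / 7.0, rel=1e-6)
        assert b.loglik == pytest.approx(a.loglik, rel=1e-9)

    def test_negative_lambda_rejected(self, rng):
        out = random_survival(rng, 30)
        with pytest.raises(ValueError):
            cox_penalized(rng.standard_normal((30, 2)), out, "ridge", -1.0)


class TestLambdaSelection:
    def test_grid_and_curve_internally_consistent(self):
        d = generate_cohort(signal_config(n_samples=60, seed=1))
        X = d.expression.values.to_numpy()
        path = select_lambda_loocv(X, d.clinical.outcome("OS"), "ridge")
        assert path.grid.size == 100
        assert np.all(np.diff(path.grid) < 0)
        assert np.all(np.isfinite(path.cv_deviance))
        assert path.cv_deviance[path.chosen_index] == path.cv_deviance.min()
        assert path.chosen_lambda == path.grid[path.chosen_index]

    def test_pure_noise_lasso_selects_empty_model(self):
        empty = 0
        for seed in range(20):
            d = generate_cohort(noise_config(n_samples=60, seed=seed))
            X = d.expression.values.to_numpy()
            out = d.clinical.outcome("OS")
            path = select_lambda_loocv(X, out, "lasso")
            fit = cox_penalized(X, out, "lasso", path.chosen_lambda)
            empty += np.all(fit.beta_std == 0.0)
        assert empty >= 14  # >= 70% of seeds

    def test_strong_signal_ranks_first_under_lasso(self):
        hits = 0
        for seed in range(20):
            d = generate_cohort(signal_config(n_samples=60, beta=1.5, seed=seed))
            X = d.expression.values.to_numpy()
            names = d.expression.gene_ids
            out = d.clinical.outcome("OS")
            path = select_lambda_loocv(X, out, "lasso")
            fit = cox_penalized(X, out, "lasso", path.chosen_lambda,
                                variables=names)
            hits += names[int(np.argmax(np.abs(fit.beta_std)))] == "G00"
        assert hits >= 19  # >= 95% of seeds

    def test_preconditions(self, rng):
        out = random_survival(rng, 8)
        with pytest.raises(ValueError, match="10 subjects"):
            select_lambda_loocv(rng.standard_normal((8, 2)), out, "ridge")


class TestLogistic:
    def test_lambda_zero_matches_newton_oracle(self, rng):
        import statsmodels.api as sm

        X = rng.standard_normal((120, 3))
        eta = 0.4 + X @ np.array([0.8, -0.5, 0.0])
        y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = logistic_penalized(X, y, penalty="none")
        Xstd = (X - X.mean(0)) / X.std(0)
        sm_fit = sm.Logit(y, sm.add_constant(Xstd)).fit(disp=0)
        assert np.allclose(fit.beta_std, sm_fit.params[1:], atol=1e-6)
        assert fit.intercept == pytest.approx(sm_fit.params[0], abs=1e-6)

    def test_infinite_penalty_gives_prevalence(self, rng):
        X = rng.standard_normal((80, 4))
        y = (rng.random(80) < 0.3).astype(float)
        fit = logistic_penalized(X, y, penalty="ridge", lambda_=1e9)
        assert np.allclose(fit.beta_std, 0.0, atol=1e-6)
        assert np.allclose(fit.predict_proba(X), y.mean(), atol=1e-4)

    def test_planted_sign_recovery(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((300, 5))
            eta = X[:, 0] * 1.0
            y = (r.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = logistic_penalized(X, y, penalty="ridge", n_lambda=20)
            hits += fit.beta_std[0] > 0
        assert hits >= 19

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            logistic_penalized(rng.standard_normal((20, 2)), np.ones(20), "ridge", 1.0)


class TestImportance:
    def _fit(self, rng):
        out = random_survival(rng, 80)
        X = rng.standard_normal((80, 4))
        return cox_penalized(X, out, "ridge", 2.0)

    def test_zero_coefficient_zero_importance(self, rng):
        fit = self._fit(rng)
        fit.beta_std[2] = 0.0
        tbl = importance_s36(fit)
        assert tbl.loc[tbl.variable == "x2", "delta_s"].iloc[0] == 0.0

    def test_closed_form_example(self, rng):
        """S=0.6 and beta*=ln2 give delta = 0.6^2 - 0.6 = -0.24."""
        fit = self._fit(rng)
        s = fit.baseline_survival(36.0)
        tbl = importance_s36(fit)
        fit.beta_std[:] = np.log(2.0)
        tbl2 = importance_s36(fit)
        expected = s**2 - s
        assert tbl2["delta_s"].iloc[0] == pytest.approx(expected, abs=1e-12)
        del tbl

    def test_sign_opposite_to_coefficient(self, rng):
        fit = self._fit(rng)
        tbl = importance_s36(fit)
        s = tbl["s_horizon_ref"].iloc[0]
        if 0 < s < 1:
            nz = tbl[tbl.beta_std != 0]
            assert np.all(np.sign(nz.delta_s) == -np.sign(nz.beta_std))

    def test_ranking_by_abs_beta_matches_abs_delta(self, rng):
        fit = self._fit(rng)
        tbl = importance_s36(fit)
        by_delta = tbl["delta_s"].abs().rank(ascending=False, method="first")
        assert (tbl["rank"].to_numpy() == by_delta.to_numpy()).all()


class TestEngineInternals:
    def test_partial_loglik_matches_direct_summation(self, rng):
        for _ in range(10):
            out = random_survival(rng, 25)
            X = rng.standard_normal((25, 2))
            beta = rng.standard_normal(2)
            _, _, Xs, _, delta, first, last = _sorted_arrays(out, X)
            got = _engine.cox_loglik(Xs, delta, np.ones(25), first, last, beta)
            # direct summation uses original (unsorted) arrays
            want = -_oracles.breslow_neg_loglik(beta, X, out.time, out.event)
            assert got == pytest.approx(want, rel=1e-10)

    def test_cv_deviance_matches_independent_refits(self, rng):
        """The fused quasi-Newton CV kernel equals per-fold full Newton."""
        out = random_survival(rng, 40)
        X = rng.standard_normal((40, 5))
        Xstd, _, _ = standardize(X)
        _, _, Xs, XsT, delta, first, last = _sorted_arrays(out, Xstd)
        w = np.ones(40)
        lam_max = _engine.null_score_max(Xs, XsT, delta, w, first, last)
        grid = lambda_grid(lam_max, "ridge", n_lambda=25)
        dev = _engine.cv_deviance_loo(Xs, XsT, delta, w, first, last, grid,
                                      False, 1e-5, 100)
        dev_ref = np.zeros(grid.size)
        for i in range(40):
            wf = np.ones(40)
            wf[i] = 0.0
            b = np.zeros(5)
            for k, lam in enumerate(grid):
                b, _, _, _ = _engine.newton_ridge(
                    Xs, XsT, delta, wf, first, last, lam, b, 1e-10, 200
                )
                l_all = _engine.cox_loglik(Xs, delta, w, first, last, b)
                l_wo = _engine.cox_loglik(Xs, delta, wf, first, last, b)
                dev_ref[k] += -2 * (l_all - l_wo)
        assert np.allclose(dev, dev_ref, rtol=1e-5, atol=1e-3)
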