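"""Cross-validated predictors and their performance measures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigsurv.data import SurvivalOutcome
from sigsurv.evaluate import (
    ModelSpec,
    added_value_test,
    c_index,
    compare_models,
    global_p,
    loocv_predictors,
    pev,
    repeated_kfold_response,
    risk_groups_km,
)
from sigsurv.simulate import SyntheticConfig, generate_cohort

import _oracles
from conftest import noise_config, random_survival, signal_config


def weibull_outcome(rng, eta, shape=1.2, scale=60.0, c_lo=12.0, c_hi=48.0):
    """Survival driven by a given linear predictor, uniform censoring."""
    n = eta.size
    t = scale * (rng.exponential(size=n) * np.exp(-eta)) ** (1 / shape)
    c = rng.uniform(c_lo, c_hi, n)
    return SurvivalOutcome(np.maximum(np.minimum(t, c), 1e-3), (t <= c).astype(int))


class TestCIndex:
    def test_perfect_concordance(self):
        out = SurvivalOutcome(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        assert c_index(np.array([3.0, 2.0, 1.0]), out) == 1.0

    def test_constant_predictor_half(self):
        out = SurvivalOutcome(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        assert c_index(np.zeros(3), out) == 0.5

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 31))
            t = rng.integers(1, 10, n).astype(float)  # ties likely
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            eta = np.round(rng.standard_normal(n), 1)  # prediction ties too
            out = SurvivalOutcome(t, e)
            try:
                want = _oracles.cindex_pairs(eta, t, e)
            except ZeroDivisionError:
                with pytest.raises(ValueError):
                    c_index(eta, out)
                continue
            assert c_index(eta, out) == want

    def test_no_usable_pairs_rejected(self):
        out = SurvivalOutcome(np.array([5.0, 5.0]), np.array([1, 1]))
        with pytest.raises(ValueError, match="usable"):
            c_index(np.array([1.0, 2.0]), out)


class TestPEV:
    def test_constant_predictor_exactly_zero(self, rng):
        out = random_survival(rng, 60)
        assert pev(np.full(60, 3.7), out) == 0.0

    def test_bounded_on_battery(self, rng):
        for _ in range(10):
            out = random_survival(rng, 50)
            eta = rng.standard_normal(50)
            v = pev(eta, out)
            assert 0.0 <= v <= 1.0

    def test_matches_straightline_oracle(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            eta = r.standard_normal(45)
            out = weibull_outcome(r, 0.8 * eta)
            got = pev(eta, out)
            want = _oracles.schemper_henderson_pev(eta, out.time, out.event)
            assert got == pytest.approx(want, abs=2e-4)

    def test_monotone_in_planted_effect_size(self):
        """Median PEV strictly increases over beta* in {0, 0.5, 1.0, 1.5}."""
        medians = []
        for beta in (0.0, 0.5, 1.0, 1.5):
            vals = []
            for seed in range(20):
                r = np.random.default_rng(1000 + seed)
                x = r.standard_normal(300)
                out = weibull_outcome(r, beta * x)
                vals.append(pev(x, out))
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2] < medians[3]

    def test_invariant_to_linear_rescaling(self, rng):
        out = random_survival(rng, 60)
        eta = rng.standard_normal(60)
        assert pev(eta, out) == pytest.approx(pev(3.0 * eta - 7.0, out), abs=1e-10)

    def test_needs_events(self):
        out = SurvivalOutcome(np.arange(1.0, 11.0), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            pev(np.arange(10.0), out)


class TestGlobalP:
    def test_constant_predictor_p_one(self, rng):
        out = random_survival(rng, 30)
        with pytest.warns(UserWarning, match="constant"):
            assert global_p(np.ones(30), out) == 1.0

    def test_null_type_i_error_calibrated(self, rng):
        ps = []
        for _ in range(200):
            out = random_survival(rng, 80)
            ps.append(global_p(rng.standard_normal(80), out))
        ps = np.array(ps)
        rej = (ps < 0.05).mean()
        # 95% binomial band around 0.05 at 200 reps
        assert 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / 200) <= rej <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / 200) + 1e-12
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_signal_detected(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            eta = r.standard_normal(150)
            out = weibull_outcome(r, 1.0 * eta)
            hits += global_p(eta, out) < 0.001
        assert hits >= 19


class TestAddedValue:
    def test_duplicate_predictor_no_added_value(self, rng):
        out = random_survival(rng, 60)
        eta = rng.standard_normal(60)
        with pytest.warns(UserWarning, match="collinear"):
            p = added_value_test(eta, eta.copy(), out)
        assert p > 0.5

    def test_null_omics_uniform(self, rng):
        ps = []
        for _ in range(100):
            r = rng
            eta_c = r.standard_normal(80)
            out = weibull_outcome(r, 0.7 * eta_c)
            ps.append(added_value_test(eta_c, r.standard_normal(80), out))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_omics_only_signal_detected(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(300 + seed)
            eta_o = r.standard_normal(200)
            eta_c = r.standard_normal(200)  # pure noise clinical predictor
            out = weibull_outcome(r, 0.9 * eta_o)
            hits += added_value_test(eta_c, eta_o, out) < 0.01
        assert hits >= 18  # >= 90% of seeds


class TestRiskGroups:
    def test_two_group_logrank_hand_example(self):
        """Group A events at 1,2; group B events at 3,4: chi2 ~ 2.882."""
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        oracle = _oracles.logrank_chi2(time, event, np.array(["a", "a", "b", "b"]))
        assert oracle == pytest.approx(2.882, abs=5e-4)
        from lifelines.statistics import multivariate_logrank_test

        res = multivariate_logrank_test(time, np.array(["a", "a", "b", "b"]), event)
        assert res.test_statistic == pytest.approx(oracle, abs=1e-9)

    def test_identical_groups_zero_chi2(self):
        eta = np.arange(12.0)
        time = np.array([5.0, 10, 15, 5, 5, 10, 10, 15, 15, 5, 10, 15])
        event = np.ones(12, dtype=int)
        strat = risk_groups_km(eta, SurvivalOutcome(time, event))
        assert strat.logrank_chi2 == pytest.approx(0.0, abs=1e-10)

    def test_km_without_censoring_is_empirical_survival(self, rng):
        t = rng.integers(1, 20, 40).astype(float)
        out = SurvivalOutcome(t, np.ones(40, dtype=int))
        strat = risk_groups_km(rng.standard_normal(40), out)
        for g, curve in strat.km_curves.items():
            sel = strat.groups.to_numpy() == g
            tg = t[sel]
            for _, row in curve.iterrows():
                emp = (tg > row["time"]).mean()
                assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_quartile_boundary_goes_intermediate(self):
        eta = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        out = SurvivalOutcome(np.arange(1.0, 9.0), np.ones(8, dtype=int))
        strat = risk_groups_km(eta, out)
        q1, q3 = strat.thresholds
        labels = strat.groups.to_numpy()
        assert ((eta < q1) == (labels == "low")).all()
        assert ((eta > q3) == (labels == "high")).all()

    def test_groups_partition_cohort(self, rng):
        out = random_survival(rng, 40)
        strat = risk_groups_km(rng.standard_normal(40), out)
        assert strat.groups.isin(["low", "intermediate", "high"]).all()
        assert len(strat.groups) == 40

    def test_minimum_size_enforced(self, rng):
        with pytest.raises(ValueError):
            risk_groups_km(rng.standard_normal(5), random_survival(rng, 5))


class TestLOOCVPredictors:
    def test_deterministic(self):
        d = generate_cohort(SyntheticConfig(n_samples=40, seed=11))
        spec = ModelSpec("clinics", "ridge", "OS")
        a = loocv_predictors(d, spec, n_lambda=30)
        b = loocv_predictors(d, spec, n_lambda=30)
        pd.testing.assert_series_equal(a.eta, b.eta)

    def test_invariant_to_sample_order(self):
        from sigsurv.data import ClinicalTable, CohortDataset, ExpressionMatrix

        d = generate_cohort(SyntheticConfig(n_samples=45, seed=14))
        spec = ModelSpec("immune", "ridge", "OS")
        a = loocv_predictors(d, spec, n_lambda=30)
        perm = np.random.default_rng(0).permutation(45)
        d2 = CohortDataset(
            expression=ExpressionMatrix(d.expression.values.iloc[perm], "log2"),
            clinical=ClinicalTable(d.clinical.table.iloc[perm]),
            signature=d.signature,
            true_subtype=d.true_subtype.iloc[perm],
        )
        b = loocv_predictors(d2, spec, n_lambda=30)
        joined = a.eta.to_frame("a").join(b.eta.rename("b"))
        assert np.allclose(joined["a"], joined["b"], atol=1e-10)

    def test_preconditions(self):
        d = generate_cohort(SyntheticConfig(n_samples=15, seed=1))
        with pytest.raises(ValueError):
            loocv_predictors(d, ModelSpec("clinics", "ridge", "OS"))


class TestCompareModels:
    def test_reports_all_requested_sets_with_added_value(self):
        d = generate_cohort(SyntheticConfig(n_samples=45, seed=13))
        tbl, preds = compare_models(
            d, outcome="OS", penalty="ridge",
            variable_sets=("clinics", "immune"), n_lambda=25,
        )
        assert list(tbl["variable_set"]) == ["clinics", "immune"]
        assert np.isnan(tbl.loc[0, "added_value_p"]) or tbl.loc[0, "added_value_p"] is None
        assert 0 <= tbl.loc[1, "added_value_p"] <= 1
        for vs in ("clinics", "immune"):
            assert len(preds[vs].eta) == 45
        assert (tbl["pev_percent"] >= 0).all()
        assert tbl["c_index"].between(0, 1).all()


class TestRepeatedKFoldResponse:
    def test_same_seed_identical_summaries(self):
        d = generate_cohort(SyntheticConfig(n_samples=60, seed=21))
        spec = ModelSpec("immune", "ridge", "response")
        a = repeated_kfold_response(d, spec, k=3, repeats=2, seed=5, n_lambda=12)
        b = repeated_kfold_response(d, spec, k=3, repeats=2, seed=5, n_lambda=12)
        assert a.auc_mean == b.auc_mean
        assert np.array_equal(a.auc_per_repeat, b.auc_per_repeat)

    def test_null_response_auc_near_half(self):
        cfg = noise_config(n_samples=200, n_genes=10, seed=31)
        d = generate_cohort(cfg)
        spec = ModelSpec("sphingo", "ridge", "response")
        rep = repeated_kfold_response(d, spec, k=5, repeats=3, seed=1, n_lambda=12)
        assert 0.45 <= rep.auc_mean <= 0.55

    def test_planted_response_signal_recovered(self):
        cfg = noise_config(
            n_samples=200, n_genes=10, seed=33,
            beta_true_response={"G00": 1.0, "G01": 1.0, "G02": 1.0},
            response_intercept=0.0,
        )
        d = generate_cohort(cfg)
        spec = ModelSpec("sphingo", "ridge", "response")
        rep = repeated_kfold_response(d, spec, k=5, repeats=3, seed=1, n_lambda=12)
        assert rep.auc_mean >= 0.70

    def test_small_class_rejected(self):
        cfg = noise_config(n_samples=30, seed=2, response_intercept=4.0)
        d = generate_cohort(cfg)
        with pytest.raises(ValueError):
            repeated_kfold_response(
                d, ModelSpec("sphingo", "ridge", "response"), k=8, repeats=1, seed=0
            )
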