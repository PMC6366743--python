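"""Updating methods 1-5, LR testing, shrinkage, stepwise development."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

import riskupdate as ru
from riskupdate import updating as up
from riskupdate.cohort import CohortConfig, generate_cohort
from riskupdate.performance import c_statistic, eo_ratio
from riskupdate.registry import PredictorSpec, RiskModel
from riskupdate.updating import (
    LP_TERM,
    FitError,
    SeparationError,
    develop_model,
    development_candidates,
    lr_test,
    method1_intercept_adjustment,
    method2_logistic_calibration,
    method3_revision,
    method4_reestimation,
    method5_extension,
    parameterwise_shrinkage,
)


def _probs(model, data):
    return np.asarray(ru.predict_risk(ru.linear_predictor(data, model)))


def _linear_model(coefs, intercept=0.0, name="toy"):
    specs = [PredictorSpec(k, "continuous", {"type": "linear", "field": k}) for k in coefs]
    return RiskModel(name, intercept, dict(coefs), specs)


class TestLRTest:
    def test_equal_logliks_give_p_one(self):
        assert lr_test(-10.0, -10.0, df=1).p_value == 1.0

    def test_chi_square_critical_value(self):
        res = lr_test(-10.0, -10.0 + 3.841 / 2, df=1)
        assert res.p_value == pytest.approx(0.050, abs=5e-4)

    def test_zero_statistic_multi_df(self):
        assert lr_test(-5.0, -5.0, df=3).p_value == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lr_test(-5.0, -5.0, df=0)
        with pytest.raises(ValueError):
            lr_test(-5.0, -6.0, df=1)


class TestMethod1:
    def test_closed_form_correction(self):
        # constant predicted risk expit(-1)=0.2689 against 50% prevalence
        model = RiskModel("const", -1.0, {}, [])
        data = pd.DataFrame({"outcome": [1.0, 0.0] * 20})
        res = method1_intercept_adjustment(model, data)
        assert res.correction_factor == pytest.approx(1.0, abs=1e-12)
        assert res.final_model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_identity_when_calibrated(self, registry, clean_cohort):
        model = registry["omani"].with_updates(
            intercept=clean_cohort.attrs["true_intercept"]
        )
        res = method1_intercept_adjustment(model, clean_cohort)
        # data simulated from this model: only sampling noise remains
        assert abs(res.correction_factor) < 0.25

    def test_degenerate_prevalence_raises(self):
        model = RiskModel("const", -1.0, {}, [])
        with pytest.raises(ValueError):
            method1_intercept_adjustment(model, pd.DataFrame({"outcome": [0.0] * 5}))


class TestCStatisticInvariance:
    @pytest.mark.parametrize("model_name", ["cambridge", "omani", "finnish"])
    def test_methods_1_2_preserve_discrimination(self, registry, prepared, model_name):
        """Affine LP transforms cannot change rank-based discrimination."""
        model = registry[model_name]
        train = prepared["train"]
        y = train["outcome"].to_numpy()
        # 12-decimal snap: decimal-coincident coefficient sums (e.g. Omani
        # 1.80+0.69+0.73 = 2.30+0.38+0.54) tie in reals but not in floats
        c0 = c_statistic(np.round(_probs(model, train), 12), y).estimate
        r1 = method1_intercept_adjustment(model, train)
        r2 = method2_logistic_calibration(model, train)
        assert r2.calibration_slope > 0
        c1 = c_statistic(np.round(_probs(r1.final_model, train), 12), y).estimate
        c2 = c_statistic(np.round(_probs(r2.final_model, train), 12), y).estimate
        assert c1 == pytest.approx(c0, abs=1e-12)
        assert c2 == pytest.approx(c0, abs=1e-12)


class TestMethod2:
    def test_self_consistency_on_own_data(self, registry):
        """Fitting the generating model recovers slope 1, intercept 0."""
        coh = generate_cohort(
            CohortConfig(n_recruited=5000, n_previously_diagnosed=0, seed=1)
        )
        model = registry["omani"].with_updates(intercept=coh.attrs["true_intercept"])
        res = method2_logistic_calibration(model, coh)
        assert res.calibration_intercept == pytest.approx(0.0, abs=0.30)
        assert res.calibration_slope == pytest.approx(1.0, abs=0.15)

    def test_shuffled_outcome_gives_zero_slope(self, registry):
        coh = generate_cohort(
            CohortConfig(n_recruited=5000, n_previously_diagnosed=0, seed=2)
        )
        rng = np.random.default_rng(0)
        coh["outcome"] = rng.permutation(coh["outcome"].to_numpy())
        model = registry["omani"].with_updates(intercept=coh.attrs["true_intercept"])
        res = method2_logistic_calibration(model, coh)
        assert abs(res.calibration_slope) < 0.15

    def test_training_eo_is_one(self, registry, prepared):
        train = prepared["train"]
        res = method2_logistic_calibration(registry["kuwaiti"], train)
        assert eo_ratio(_probs(res.final_model, train), train["outcome"]) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_zero_variance_lp_raises(self):
        model = RiskModel("const", -1.0, {}, [])
        with pytest.raises(FitError):
            method2_logistic_calibration(model, pd.DataFrame({"outcome": [1.0, 0.0] * 10}))


def test_nested_loglik_ordering(registry, prepared):
    """Each nested enlargement of the fitted family cannot lose likelihood."""
    train = prepared["train"]
    for name, model in registry.items():
        ll0 = up.log_likelihood(model, train)
        r1 = method1_intercept_adjustment(model, train)
        r2 = method2_logistic_calibration(model, train)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r3 = method3_revision(model, train, shrink=False)
        assert r1.loglik >= ll0 - 1e-9, name
        assert r2.loglik >= r1.loglik - 1e-9, name
        assert r3.loglik >= r2.loglik - 1e-9, name


class TestMethod3:
    def test_tiny_alpha_collapses_to_method2(self, registry, prepared):
        train = prepared["train"]
        model = registry["omani"]
        r2 = method2_logistic_calibration(model, train)
        r3 = method3_revision(model, train, alpha=1e-12)
        assert r3.selected == [] and r3.deviations == {}
        assert r3.final_model.intercept == pytest.approx(r2.final_model.intercept)
        for t in model.terms:
            assert r3.final_model.coefficients[t] == pytest.approx(
                r2.final_model.coefficients[t]
            )

    def test_detects_doubled_coefficient(self, registry):
        base = registry["omani"].with_updates(intercept=-5.356)
        coefs = dict(base.coefficients)
        coefs["bmi_30_plus"] *= 2
        gen = base.with_updates(coefficients=coefs, name="shifted")
        coh = generate_cohort(
            CohortConfig(n_recruited=5000, n_previously_diagnosed=0,
                         true_model=gen, target_prevalence=None, seed=33)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = method3_revision(base, coh, shrink=False)
        assert "bmi_30_plus" in res.selected
        assert res.deviations["bmi_30_plus"] > 0

    def test_screening_records_tests(self, registry, prepared):
        res = method3_revision(registry["kuwaiti"], prepared["train"], shrink=False)
        assert set(res.screening) | set(res.failures) == set(registry["kuwaiti"].terms)
        for t in res.screening.values():
            assert t.statistic >= 0 and 0 <= t.p_value <= 1


class TestMethod4:
    def test_matches_generic_optimizer_on_toy_data(self):
        """ML fit agrees with direct likelihood maximisation to 1e-6."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 3))
        y = np.array([1, 0, 1, 0, 0, 1, 0, 1, 0, 0, 1, 0], dtype=float)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["outcome"] = y
        model = _linear_model({"a": 1.0, "b": 1.0, "c": 1.0})
        res = method4_reestimation(model, df, shrink=False)

        Xd = np.column_stack([np.ones(12), X])

        def nll(beta):
            eta = Xd @ beta
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        opt = minimize(nll, np.zeros(4), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 500})
        got = np.array([res.free_intercept] + [res.free_coefficients[t] for t in "abc"])
        assert np.max(np.abs(got - opt.x)) < 1e-6

    def test_training_eo_one_after_shrinkage(self, registry, prepared):
        train = prepared["train"]
        res = method4_reestimation(registry["omani"], train, B=50, seed=0)
        assert eo_ratio(_probs(res.final_model, train), train["outcome"]) == pytest.approx(
            1.0, abs=1e-6
        )
        assert all(0 <= f <= 1.5 for f in res.shrinkage_factors.values())

    def test_perfect_association_raises_separation(self):
        df = pd.DataFrame({"x": [0.0, 0, 0, 1, 1, 1], "outcome": [0.0, 0, 0, 1, 1, 1]})
        model = _linear_model({"x": 1.0})
        with pytest.raises(SeparationError, match="x"):
            method4_reestimation(model, df, shrink=False)

    def test_constant_term_raises_named_error(self, registry, prepared):
        train = prepared["train"].copy()
        train["corticosteroids"] = 0
        with pytest.raises(FitError, match="corticosteroids"):
            method4_reestimation(registry["cambridge"], train, shrink=False)


class TestMethod5:
    def test_empty_candidates_reduce_to_method2(self, registry, prepared):
        train = prepared["train"]
        r2 = method2_logistic_calibration(registry["omani"], train)
        r5 = method5_extension(registry["omani"], train, candidates=[])
        assert r5.selected == []
        assert r5.final_model.intercept == pytest.approx(r2.final_model.intercept)

    def test_strong_extra_predictor_selected_and_improves(self, registry):
        """An omitted strong predictor is recovered and helps out of sample."""
        base = registry["rotterdam"]
        coh = generate_cohort(
            CohortConfig(n_recruited=4000, n_previously_diagnosed=0, seed=44)
        )  # truth is the Omani model: waist/family-history signal absent from Rotterdam
        from riskupdate.preprocessing import split_cohort

        sp = split_cohort(coh, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r5 = method5_extension(base, sp.train, B=50, seed=0)
            r2 = method2_logistic_calibration(base, sp.train)
        assert r5.selected  # something real to find
        y = sp.test["outcome"].to_numpy()
        c5 = c_statistic(_probs(r5.final_model, sp.test), y).estimate
        c2 = c_statistic(_probs(r2.final_model, sp.test), y).estimate
        assert c5 > c2

    def test_candidate_collision_raises(self, registry, prepared):
        block = up.CandidateBlock(
            "bmi", (PredictorSpec("bmi_30_plus", "derived-binary",
                                  {"type": "range", "field": "bmi", "lo": 30.0, "hi": None}),)
        )
        with pytest.raises(ValueError, match="collides"):
            method5_extension(registry["omani"], prepared["train"], candidates=[block])


class TestShrinkage:
    def test_large_sample_factors_near_one(self):
        rng = np.random.default_rng(5)
        n = 10000
        X = rng.standard_normal((n, 3))
        beta = np.array([0.8, -0.5, 0.3])
        y = (rng.random(n) < expit(-1.5 + X @ beta)).astype(float)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["outcome"] = y
        model = _linear_model({"a": 1.0, "b": 1.0, "c": 1.0})
        res = method4_reestimation(model, df, B=50, seed=1)
        for f in res.shrinkage_factors.values():
            assert f == pytest.approx(1.0, abs=0.1)

    def test_overfit_noise_model_shrinks(self):
        rng = np.random.default_rng(6)
        n, k = 120, 10
        X = rng.standard_normal((n, k))
        y = (rng.random(n) < 0.3).astype(float)
        cols = [f"v{i}" for i in range(k)]
        df = pd.DataFrame(X, columns=cols)
        df["outcome"] = y
        model = _linear_model({c: 1.0 for c in cols})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = method4_reestimation(model, df, B=100, seed=2)
        assert np.mean(list(res.shrinkage_factors.values())) < 1.0

    def test_small_b_warns(self, registry, prepared):
        with pytest.warns(UserWarning, match="small"):
            method4_reestimation(registry["omani"], prepared["train"], B=20, seed=0)

    def test_requires_free_coefficients(self, registry, prepared):
        r2 = method2_logistic_calibration(registry["omani"], prepared["train"])
        with pytest.raises(ValueError):
            parameterwise_shrinkage(r2, prepared["train"])


class TestDevelop:
    def test_alpha_one_keeps_full_model(self, clean_cohort):
        pool = {b.name: b for b in development_candidates()}
        cands = [pool[k] for k in ("age", "bmi", "smoking")]
        res = develop_model(clean_cohort, candidates=cands, alpha=1.0, shrink=False)
        assert sorted(res.selected) == ["age", "bmi", "smoking"]

    def test_recovers_generating_terms(self):
        """Strong three-block truth is recovered by backward selection."""
        pool = {b.name: b for b in development_candidates()}
        cands = [pool[k] for k in ("sex", "age", "bmi", "antihypertensive")]
        hits = 0
        for s in range(10):
            coh = generate_cohort(
                CohortConfig(n_recruited=5000, n_previously_diagnosed=0, seed=60 + s)
            )
            rng = np.random.default_rng(160 + s)
            lp = (-6.0 + 0.06 * coh["age"].to_numpy()
                  + 1.2 * (coh["bmi"].to_numpy() >= 30)
                  + 1.0 * coh["antihypertensive_meds"].to_numpy())
            coh["outcome"] = (rng.random(len(coh)) < expit(lp)).astype(float)
            res = develop_model(coh, candidates=cands, shrink=False)
            hits += sorted(res.selected) == ["age", "antihypertensive", "bmi"]
        assert hits >= 8

    def test_null_outcome_retains_little(self):
        kept = []
        intercept_only = 0
        for s in range(10):
            coh = generate_cohort(
                CohortConfig(n_recruited=1083, n_previously_diagnosed=0, seed=500 + s)
            )
            rng = np.random.default_rng(600 + s)
            coh["outcome"] = rng.permutation(coh["outcome"].to_numpy())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = develop_model(coh, shrink=False)
            kept.append(len(res.selected))
            intercept_only += not res.selected
        assert np.mean(kept) <= 1.0
        assert intercept_only >= 1

    def test_intercept_only_fallback(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "age": rng.uniform(20, 90, 200),
            "outcome": (rng.random(200) < 0.3).astype(float),
        })
        pool = {b.name: b for b in development_candidates()}
        with pytest.warns(UserWarning, match="intercept-only"):
            res = develop_model(df, candidates=[pool["age"]], alpha=1e-9)
        assert res.final_model.coefficients == {}
        assert res.final_model.intercept == pytest.approx(
            logit(df["outcome"].mean()), abs=1e-6
        )

    def test_training_eo_one(self, prepared):
        train = prepared["train"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = develop_model(train, B=50, seed=0)
        assert eo_ratio(_probs(res.final_model, train), train["outcome"]) == pytest.approx(
            1.0, abs=1e-6
        )


def test_final_model_reproduces_composed_formula(registry, prepared):
    """Materialized models equal a + b*LP (+ deviations) to 1e-12."""
    train = prepared["train"]
    model = registry["finnish"]
    r2 = method2_logistic_calibration(model, train)
    lp = np.asarray(ru.linear_predictor(train, model))
    composed = r2.calibration_intercept + r2.calibration_slope * lp
    assert np.max(np.abs(np.asarray(ru.linear_predictor(train, r2.final_model)) - composed)) < 1e-12
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r3 = method3_revision(registry["omani"], train, shrink=False)
    if r3.selected:
        from riskupdate.registry import design_matrix

        dm = design_matrix(train, registry["omani"])
        lp_o = np.asarray(ru.linear_predictor(train, registry["omani"]))
        composed = r3.calibration_intercept + r3.calibration_slope * lp_o
        for t, g in r3.deviations.items():
            composed = composed + g * dm[t].to_numpy()
        got = np.asarray(ru.linear_predictor(train, r3.final_model))
        assert np.max(np.abs(got - composed)) < 1e-12
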