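"""Tests for nonlinear fitting, metrics and AICc model selection."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from conftest import make_m4_truth
from ehckit.empirical import (
    EmpiricalModelSpec,
    EmpiricalParams,
    auc_closed_form,
    evaluate,
)
from ehckit.exceptions import ValidationError
from ehckit.fitting import (
    MultiPeakRegressor,
    accuracy,
    adjusted_r2,
    aicc,
    fit_profile,
    init_guess,
    select_model,
)
from ehckit.profiles import ObservedProfile
from ehckit.sampling import NoiseModel, add_noise


class TestAicc:
    def test_printed_form_reference_value(self):
        # 17 ln(0.01/8) + 2*9 + 2*9*10/7, evaluated directly
        assert aicc(0.01, 17, 9) == pytest.approx(-69.92411365606905, abs=1e-9)

    def test_standard_form_option(self):
        expected = 17 * math.log(0.01 / 17) + 18 + 180 / 7
        assert aicc(0.01, 17, 9, form="standard") == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_sse(self):
        vals = [aicc(s, 17, 9) for s in (0.001, 0.01, 0.1, 1.0)]
        assert vals == sorted(vals)

    def test_parameter_penalty_on_k_grid(self):
        # equal SSE and n: more parameters always costs AICc
        for n in (12, 17, 25, 40):
            for k in range(1, n - 2):
                assert aicc(0.5, n, k + 1) > aicc(0.5, n, k)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            aicc(0.1, 10, 9)
        with pytest.raises(ValidationError):
            aicc(0.0, 17, 9)
        with pytest.raises(ValidationError):
            aicc(0.1, 17, 9, form="nonsense")


class TestMetrics:
    def test_adjusted_r2_perfect_fit(self):
        assert adjusted_r2(0.0, 10.0, 17, 9) == 1.0

    def test_adjusted_r2_degrades_with_noise_level(self, m4_truth, meal_times):
        # the true model scored against its own noisy output: more noise,
        # lower adjusted R2 in expectation
        spec, params = m4_truth
        y = evaluate(spec, params, meal_times)
        sst_scores = {}
        for cv in (0.05, 0.3):
            vals = []
            for seed in range(100):
                rng = np.random.default_rng(seed)
                noisy = np.maximum(y * (1 + rng.normal(0, cv, y.size)), 0)
                sse = float(np.sum((noisy - y) ** 2))
                sst = float(np.sum((noisy - noisy.mean()) ** 2))
                vals.append(adjusted_r2(sse, sst, y.size, 9))
            sst_scores[cv] = np.mean(vals)
        assert sst_scores[0.3] < sst_scores[0.05]

    @pytest.mark.parametrize("est, ref, expected", [(5.0, 5.0, 100.0), (0.0, 4.0, 0.0), (5.0, 4.0, 125.0)])
    def test_accuracy(self, est, ref, expected):
        assert accuracy(est, ref) == expected

    def test_accuracy_requires_positive_reference(self):
        with pytest.raises(ValidationError):
            accuracy(1.0, 0.0)


class TestInitGuess:
    def test_deterministic(self, m4_profile):
        spec = EmpiricalModelSpec("M4", 4)
        g1 = init_guess(m4_profile, spec)
        g2 = init_guess(m4_profile, spec)
        for k in g1.values:
            np.testing.assert_array_equal(np.atleast_1d(g1[k]), np.atleast_1d(g2[k]))

    def test_onsets_near_truth(self, m4_truth, m4_profile):
        spec, params = m4_truth
        g = init_guess(m4_profile, spec)
        # each initial onset within one sampling interval of the true one
        assert np.max(np.abs(np.atleast_1d(g["d"]) - np.atleast_1d(params["d"]))) <= 5.0

    def test_monotone_profile_single_onset_at_first_sample(self):
        t = np.array([0.0, 1, 2, 4, 8, 16, 24])
        prof = ObservedProfile(t, 5.0 * np.exp(-0.3 * t))
        g = init_guess(prof, EmpiricalModelSpec("M4", 1))
        assert np.atleast_1d(g["d"])[0] == t[0]

    def test_too_few_samples_rejected(self):
        prof = ObservedProfile([0.0, 1, 2, 3], [0.0, 1, 2, 1])
        with pytest.raises(ValidationError):
            init_guess(prof, EmpiricalModelSpec("M4", 4))


class TestParameterRecovery:
    @pytest.mark.parametrize("model", ["M0", "M1", "M4", "M5"])
    def test_identifiable_models_recover_within_one_percent(self, model, meal_times):
        truth = _truth_for(model)
        n = {"M0": 1, "M1": 4, "M4": 4, "M5": 4}[model]
        spec = EmpiricalModelSpec(model, n)
        prof = ObservedProfile(meal_times, evaluate(spec, truth, meal_times))
        res = fit_profile(prof, spec, n_restarts=8)
        tv = np.concatenate([np.atleast_1d(truth[k]) for k in truth.values])
        fv = np.concatenate([np.atleast_1d(res.params[k]) for k in truth.values])
        assert np.max(np.abs(fv - tv) / np.abs(tv)) < 0.01
        assert res.adj_r2 > 0.9999
        assert res.sse < 1e-10

    @pytest.mark.parametrize(
        "model, restarts, auc_rtol",
        [("M2", 30, 0.01), ("M3", 50, 0.05)],
    )
    def test_degenerate_models_recover_the_curve_and_auc(self, model, restarts, auc_rtol, meal_times):
        # M2 and M3 admit perfect-fit impostor parameter sets (flat
        # likelihood directions), so only functional recovery is meaningful
        truth = _truth_for(model)
        spec = EmpiricalModelSpec(model, 4)
        y = evaluate(spec, truth, meal_times)
        prof = ObservedProfile(meal_times, y)
        res = fit_profile(prof, spec, n_restarts=restarts)
        assert res.adj_r2 > 0.995
        assert res.auc_inf == pytest.approx(auc_closed_form(spec, truth), rel=auc_rtol)

    def test_noisy_fits_stay_accurate_on_average(self, m4_truth, meal_times):
        spec, params = m4_truth
        y = evaluate(spec, params, meal_times)
        ref = auc_closed_form(spec, params)
        clean = ObservedProfile(meal_times, y)
        accs = []
        for seed in range(100):
            noisy = add_noise(clean, NoiseModel(0.10, 0.0, seed))
            res = fit_profile(noisy, spec, ref_auc=ref, random_state=seed)
            accs.append(res.accuracy_pct)
        assert 90 < np.mean(accs) < 110

    def test_insufficient_samples_rejected(self):
        prof = ObservedProfile([0.0, 1, 2, 3, 4], [0.0, 1, 2, 1, 0.5])
        with pytest.raises(ValidationError):
            fit_profile(prof, EmpiricalModelSpec("M4", 4))


class TestModelSelection:
    def test_multi_peak_data_ranks_tanh_models_over_biexponential(self, meal_times):
        spec, params = make_m4_truth()
        y = evaluate(spec, params, meal_times)
        noisy = add_noise(ObservedProfile(meal_times, y), NoiseModel(0.05, 0.0, 3))
        ranked = select_model(noisy, [
            EmpiricalModelSpec("M0", 1), EmpiricalModelSpec("M4", 4), EmpiricalModelSpec("M5", 4),
        ])
        order = [r.spec.model_id for r in ranked]
        assert order.index("M0") == 2  # both multi-peak models beat it

    def test_single_peak_data_keeps_biexponential_competitive(self, meal_times):
        truth = EmpiricalParams("M0", {"a": 3.0, "b": 0.12, "c": 0.8})
        y = evaluate(EmpiricalModelSpec("M0"), truth, meal_times)
        noisy = add_noise(ObservedProfile(meal_times, y), NoiseModel(0.05, 0.0, 1))
        ranked = select_model(noisy, [
            EmpiricalModelSpec("M0", 1), EmpiricalModelSpec("M4", 1), EmpiricalModelSpec("M5", 1),
        ])
        best = ranked[0].aicc
        m0 = next(r for r in ranked if r.spec.model_id == "M0")
        assert m0.aicc - best <= 2.0

    def test_ranking_invariant_to_candidate_order(self, m4_profile):
        specs = [EmpiricalModelSpec("M0", 1), EmpiricalModelSpec("M4", 4), EmpiricalModelSpec("M5", 4)]
        a = [r.spec.model_id for r in select_model(m4_profile, specs)]
        b = [r.spec.model_id for r in select_model(m4_profile, list(reversed(specs)))]
        assert a == b

    def test_gamma_gaussian_model_pays_its_parameter_cost(self, sim_80):
        # across noisy multi-peak profiles the 3n-parameter Gaussian-train
        # model carries a systematically larger AICc than M5
        from ehckit.sampling import extract_samples, scheme
        prof = extract_samples(sim_80, scheme("meal_based"))
        a1, a5 = [], []
        for seed in range(3):
            noisy = add_noise(prof, NoiseModel(0.10, 0.0, seed))
            a1.append(fit_profile(noisy, EmpiricalModelSpec("M1", 4), n_restarts=3).aicc)
            a5.append(fit_profile(noisy, EmpiricalModelSpec("M5", 4), n_restarts=3).aicc)
        assert np.mean(a5) < np.mean(a1)


class TestMultiPeakRegressor:
    def test_sklearn_contract(self):
        reg = MultiPeakRegressor(model="M4", n_peaks=2)
        params = reg.get_params()
        assert params["model"] == "M4" and params["n_peaks"] == 2
        cloned = clone(reg)
        assert cloned.get_params() == params

    def test_fit_predict_roundtrip(self, m4_truth, meal_times):
        spec, params = m4_truth
        y = evaluate(spec, params, meal_times)
        reg = MultiPeakRegressor(model="M4", n_peaks=4, n_restarts=8)
        reg.fit(meal_times, y)
        assert reg.converged_
        assert reg.adj_r2_ > 0.9999
        assert reg.auc_inf_ == pytest.approx(auc_closed_form(spec, params), rel=1e-4)
        np.testing.assert_allclose(reg.predict(meal_times), y, atol=1e-5)
        assert reg.score(meal_times, y) > 0.9999

    def test_accepts_single_column_matrix(self, m4_truth, meal_times):
        spec, params = m4_truth
        y = evaluate(spec, params, meal_times)
        reg = MultiPeakRegressor(model="M4", n_peaks=4, n_restarts=2)
        reg.fit(meal_times.reshape(-1, 1), y)
        assert reg.predict(meal_times.reshape(-1, 1)).shape == y.shape

    def test_predict_before_fit_raises(self):
        with pytest.raises(ValidationError):
            MultiPeakRegressor().predict([0.0, 1.0])


def _truth_for(model: str) -> EmpiricalParams:
    if model == "M0":
        return EmpiricalParams("M0", {"a": 3.0, "b": 0.12, "c": 0.8})
    if model == "M1":
        return EmpiricalParams("M1", {"a": 0.4, "b": 0.35, "c": 2.0,
                                      "d": [0.8, 0.55, 0.4], "f": [6.0, 12.0, 18.0],
                                      "g": [1.2, 1.4, 1.6]})
    if model == "M2":
        return EmpiricalParams("M2", {"a": 0.12, "b": [2.0, 1.2, 0.9, 0.7],
                                      "c": [2.0, 4.0, 4.5, 5.0], "d": [5.0, 45.0, 52.0, 88.0]})
    if model == "M3":
        return EmpiricalParams("M3", {"a": 0.3, "b": [0.6, 0.5, 0.45, 0.4],
                                      "c": [0.0, 5.0, 11.0, 17.0], "d": [1.5, 2.0, 2.0, 2.0]})
    _, p4 = make_m4_truth()
    if model == "M4":
        return p4
    return EmpiricalParams("M5", dict(p4.values))
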