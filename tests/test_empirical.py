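"""Tests for the empirical multi-peak models and their closed-form AUC."""

import math

import numpy as np
import pytest

from conftest import random_model_params
from ehckit.empirical import (
    MODEL_IDS,
    EmpiricalModelSpec,
    EmpiricalParams,
    auc_closed_form,
    evaluate,
    m5_envelope_rate,
    param_count,
    structural_param_count,
)
from ehckit.exceptions import DivergenceError, ValidationError


class TestParamCounts:
    @pytest.mark.parametrize(
        "model, expected",
        [
            ("M0", (3, 3, 3, 3)),
            ("M1", (5, 8, 11, 14)),
            ("M2", (4, 7, 10, 13)),
            ("M3", (4, 7, 10, 13)),
            ("M4", (3, 5, 7, 9)),
            ("M5", (3, 5, 7, 9)),
        ],
    )
    def test_published_counts(self, model, expected):
        got = tuple(param_count(EmpiricalModelSpec(model, n)) for n in (1, 2, 3, 4))
        assert got == expected

    def test_m1_structural_layout_differs_from_published(self):
        # gamma triple + one Gaussian triple per secondary peak = 3n
        assert structural_param_count(EmpiricalModelSpec("M1", 4)) == 12
        assert param_count(EmpiricalModelSpec("M1", 4)) == 14

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            EmpiricalModelSpec("M9", 1)
        with pytest.raises(ValidationError):
            EmpiricalModelSpec("M4", 0)


class TestEvaluate:
    def test_m0_starts_at_zero(self):
        p = EmpiricalParams("M0", {"a": 2.0, "b": 0.1, "c": 1.0})
        assert evaluate(EmpiricalModelSpec("M0"), p, 0.0) == 0.0

    def test_m4_zero_before_first_onset(self):
        p = EmpiricalParams("M4", {"c": 0.3, "b": [1.0, 2.0], "d": [3.0, 9.0]})
        t = np.linspace(0, 2.99, 50)
        np.testing.assert_array_equal(evaluate(EmpiricalModelSpec("M4", 2), p, t), 0.0)

    def test_tanh_equals_printed_rational_form(self):
        # (e^{2cu} - 1)/(e^{2cu} + 1) is tanh(cu): the evaluated M4 must
        # match the rational form to machine precision
        rng = np.random.default_rng(0)
        for _ in range(5):
            c = rng.uniform(0.05, 1.0)
            d = np.sort(rng.uniform(0, 10, 2))
            d[1] = max(d[1], d[0] + 0.5)
            b = rng.uniform(0.1, 3.0, 2)
            p = EmpiricalParams("M4", {"c": c, "b": b, "d": d})
            t = np.linspace(0, 40, 200)
            direct = evaluate(EmpiricalModelSpec("M4", 2), p, t)
            rational = np.zeros_like(t)
            for bi, di in zip(b, d):
                u = t - di
                e = np.exp(2 * c * np.maximum(u, 0))
                rational += np.where(u >= 0, bi * (e - 1) / (e + 1), 0.0)
            rational *= np.exp(-c * t)
            np.testing.assert_allclose(direct, rational, rtol=1e-13, atol=1e-15)

    def test_m5_equals_m4_during_first_day(self):
        vals = {"c": 0.2, "b": [3.0, 2.0, 1.5], "d": [1.0, 7.0, 13.0]}
        p4 = EmpiricalParams("M4", vals)
        p5 = EmpiricalParams("M5", vals)
        t = np.linspace(0, 24.999, 400)  # first replicate begins at d1 + 24
        np.testing.assert_array_equal(
            evaluate(EmpiricalModelSpec("M4", 3), p4, t),
            evaluate(EmpiricalModelSpec("M5", 3), p5, t),
        )
        t2 = np.linspace(25.5, 60, 100)
        assert np.all(
            evaluate(EmpiricalModelSpec("M5", 3), p5, t2)
            >= evaluate(EmpiricalModelSpec("M4", 3), p4, t2)
        )

    @pytest.mark.parametrize("model", MODEL_IDS)
    def test_non_negative_everywhere(self, model):
        rng = np.random.default_rng(11)
        spec = EmpiricalModelSpec(model, 3 if model != "M0" else 1)
        t = np.linspace(0, 120, 2000)
        for _ in range(3):
            p = random_model_params(model, rng)
            assert np.all(evaluate(spec, p, t) >= 0)

    def test_peak_count_bounded_by_n_peaks(self):
        from scipy.signal import find_peaks
        rng = np.random.default_rng(5)
        for model in ("M1", "M2", "M3", "M4"):
            spec = EmpiricalModelSpec(model, 3)
            for _ in range(3):
                p = random_model_params(model, rng)
                y = evaluate(spec, p, np.linspace(0, 80, 4000))
                peaks, _ = find_peaks(y, prominence=1e-6 * max(y.max(), 1e-12))
                assert len(peaks) <= 3

    def test_invariant_violations_raise(self):
        with pytest.raises(ValidationError):  # c must exceed b
            evaluate(EmpiricalModelSpec("M0"), EmpiricalParams("M0", {"a": 1, "b": 1.0, "c": 0.5}), 1.0)
        with pytest.raises(ValidationError):  # onsets must increase
            evaluate(EmpiricalModelSpec("M4", 2),
                     EmpiricalParams("M4", {"c": 0.2, "b": [1, 1], "d": [5.0, 3.0]}), 1.0)
        with pytest.raises(ValidationError):  # negative amplitude
            evaluate(EmpiricalModelSpec("M2", 1),
                     EmpiricalParams("M2", {"a": 0.1, "b": [-1.0], "c": [1.0], "d": [2.0]}), 1.0)


class TestClosedFormAuc:
    def test_m0_reference_value(self):
        p = EmpiricalParams("M0", {"a": 1.0, "b": 0.1, "c": 1.0})
        assert auc_closed_form(EmpiricalModelSpec("M0"), p) == pytest.approx(9.0, rel=1e-12)

    def test_m4_single_peak_reference_value(self, quad_auc):
        # frozen against the quadrature oracle: (1/c) * int e^-x tanh x dx
        spec = EmpiricalModelSpec("M4", 1)
        p = EmpiricalParams("M4", {"c": 0.1, "b": [1.0], "d": [0.0]})
        assert auc_closed_form(spec, p) == pytest.approx(5.707963267948966, rel=1e-12)
        assert quad_auc(spec, p) == pytest.approx(5.707963267948966, rel=1e-9)

    @pytest.mark.parametrize("model", MODEL_IDS)
    def test_closed_form_matches_quadrature(self, model, quad_auc):
        rng = np.random.default_rng(ord(model[1]))
        spec = EmpiricalModelSpec(model, 3 if model != "M0" else 1)
        for _ in range(3):
            p = random_model_params(model, rng)
            exact = auc_closed_form(spec, p)
            assert exact == pytest.approx(quad_auc(spec, p), rel=1e-6)

    def test_m2_literal_reading_matches_quadrature(self, quad_auc):
        spec = EmpiricalModelSpec("M2", 2)
        p = EmpiricalParams("M2", {"a": 0.15, "b": [2.0, 1.0], "c": [3.0, 2.0], "d": [5.0, 25.0]})
        exact = auc_closed_form(spec, p, m2_literal=True)
        assert exact == pytest.approx(quad_auc(spec, p, m2_literal=True), rel=1e-6)

    def test_amplitude_scaling_is_linear(self):
        rng = np.random.default_rng(3)
        for model in MODEL_IDS:
            spec = EmpiricalModelSpec(model, 3 if model != "M0" else 1)
            p = random_model_params(model, rng)
            assert auc_closed_form(spec, p.scaled(2.0)) == pytest.approx(
                2.0 * auc_closed_form(spec, p), rel=1e-12
            )

    def test_m5_exceeds_m4_on_shared_parameters(self):
        vals = {"c": 0.25, "b": [3.0, 2.0], "d": [1.0, 13.0]}
        a4 = auc_closed_form(EmpiricalModelSpec("M4", 2), EmpiricalParams("M4", vals))
        a5 = auc_closed_form(EmpiricalModelSpec("M5", 2), EmpiricalParams("M5", vals))
        assert a5 > a4

    def test_m0_invalid_rates_raise(self):
        with pytest.raises(ValidationError):
            auc_closed_form(EmpiricalModelSpec("M0"),
                            EmpiricalParams("M0", {"a": 1.0, "b": 1.0, "c": 0.5}))


class TestEnvelopeRate:
    def test_reference_value(self):
        p = EmpiricalParams("M5", {"c": 0.05, "b": [1.0, 0.5], "d": [1.0, 13.0]})
        lam = m5_envelope_rate(p)
        assert lam == pytest.approx(math.log(2) / 12 + 0.05, rel=1e-12)
        assert lam == pytest.approx(0.1077622650466621, rel=1e-12)

    def test_definition_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            p = random_model_params("M5", rng)
            c, b, d = p["c"], np.atleast_1d(p["b"]), np.atleast_1d(p["d"])
            lam = m5_envelope_rate(p)
            h = b * np.exp(-c * d)
            assert h[-1] == pytest.approx(h[0] * math.exp(-lam * (d[-1] - d[0])), rel=1e-9)
            assert math.exp(-24 * lam) < 1.0

    def test_growing_envelope_diverges(self):
        # last peak higher than the first: replicate series cannot converge
        p = EmpiricalParams("M5", {"c": 0.05, "b": [0.5, 5.0], "d": [1.0, 13.0]})
        with pytest.raises(DivergenceError):
            m5_envelope_rate(p)
        with pytest.raises(DivergenceError):
            auc_closed_form(EmpiricalModelSpec("M5", 2), p)

    def test_single_peak_has_no_envelope(self):
        p = EmpiricalParams("M5", {"c": 0.1, "b": [1.0], "d": [2.0]})
        with pytest.raises(ValidationError):
            m5_envelope_rate(p)
        # ... but evaluation and AUC remain defined (replicates follow the
        # elimination envelope)
        assert auc_closed_form(EmpiricalModelSpec("M5", 1), p) > 0
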