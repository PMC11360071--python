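"""Shared fixtures: reference simulations, synthetic truths, oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad

from ehckit.empirical import EmpiricalModelSpec, EmpiricalParams, evaluate
from ehckit.profiles import ObservedProfile
from ehckit.sampling import scheme
from ehckit.scenarios import standard_params
from ehckit.simulator import simulate


@pytest.fixture(scope="session")
def meal_times() -> np.ndarray:
    return np.array(scheme("meal_based").times)


@pytest.fixture(scope="session")
def sim_80():
    """Standard model at the 80% EHC level (case A high, negligible competition)."""
    return simulate(standard_params(km=10.0, kehc=0.4))


@pytest.fixture(scope="session")
def sim_40():
    """Standard model at the 40% EHC level."""
    return simulate(standard_params(km=10.0, kehc=0.0666))


@pytest.fixture(scope="session")
def sim_single_peak():
    """No biliary recycling: a single-peak absorption profile."""
    return simulate(standard_params(km=10.0, kehc=0.0))


def make_m4_truth() -> tuple[EmpiricalModelSpec, EmpiricalParams]:
    """A 4-peak sawtooth truth: peak heights 1.2/0.8/0.6/0.45 mg/L at
    onsets 0.5/5.5/11.5/17.5 h under elimination rate 0.35 1/h."""
    c = 0.35
    d = np.array([0.5, 5.5, 11.5, 17.5])
    h = np.array([1.2, 0.8, 0.6, 0.45])
    params = EmpiricalParams("M4", {"c": c, "b": h * np.exp(c * d), "d": d})
    return EmpiricalModelSpec("M4", 4), params


@pytest.fixture(scope="session")
def m4_truth():
    return make_m4_truth()


@pytest.fixture(scope="session")
def m4_profile(m4_truth, meal_times) -> ObservedProfile:
    spec, params = m4_truth
    return ObservedProfile(meal_times, evaluate(spec, params, meal_times))


def quadrature_auc(spec: EmpiricalModelSpec, params: EmpiricalParams, **kw) -> float:
    """Independent day-by-day adaptive-quadrature AUC oracle.

    Integrates the evaluated curve over successive 24 h windows (with
    quadrature breakpoints at the onset discontinuities) until a window
    contributes less than 1e-12 of the running total.
    """
    def f(t):
        return evaluate(spec, params, t, **kw)

    onsets = []
    v = params.values
    if spec.model_id in ("M4", "M5"):
        onsets = list(np.atleast_1d(v["d"]))
    elif spec.model_id == "M3":
        onsets = list(np.atleast_1d(v["c"]))
    total = 0.0
    t0 = 0.0
    for day in range(2000):
        t1 = t0 + 24.0
        pts = sorted({t0 + (o % 24.0) for o in onsets} | {t0, t1})
        val = 0.0
        for a, b in zip(pts, pts[1:]):
            val += quad(f, a, b, limit=200)[0]
        total += val
        if day >= 4 and abs(val) < 1e-12 * max(abs(total), 1e-30):
            break
        t0 = t1
    return total


@pytest.fixture(scope="session")
def quad_auc():
    return quadrature_auc


def random_model_params(model_id: str, rng: np.random.Generator, n_peaks: int = 3):
    """A random valid parameter set per model (separated peaks, decaying
    envelope) for closed-form-vs-quadrature cross checks."""
    n = n_peaks
    onsets = np.sort(rng.uniform(0.5, 20.0, n))
    onsets += np.arange(n) * 1.0  # enforce separation
    if model_id == "M0":
        b = rng.uniform(0.05, 0.3)
        return EmpiricalParams("M0", {"a": rng.uniform(0.5, 5.0), "b": b,
                                      "c": b + rng.uniform(0.2, 2.0)})
    if model_id == "M1":
        return EmpiricalParams("M1", {
            "a": rng.uniform(0.1, 1.0), "b": rng.uniform(0.1, 0.5),
            "c": rng.uniform(0.5, 3.0),
            "d": rng.uniform(0.1, 1.0, n - 1), "f": onsets[1:],
            "g": rng.uniform(0.5, 3.0, n - 1),
        })
    if model_id == "M2":
        return EmpiricalParams("M2", {
            "a": rng.uniform(0.05, 0.3), "b": rng.uniform(0.2, 3.0, n),
            "c": rng.uniform(0.5, 5.0, n), "d": rng.uniform(2.0, 60.0, n),
        })
    if model_id == "M3":
        return EmpiricalParams("M3", {
            "a": rng.uniform(0.1, 0.5), "b": rng.uniform(0.05, 1.0, n),
            "c": onsets, "d": rng.uniform(0.3, 3.0, n),
        })
    c = rng.uniform(0.1, 0.6)
    heights = np.sort(rng.uniform(0.2, 2.0, n))[::-1]  # decaying envelope
    b = heights * np.exp(c * onsets)
    return EmpiricalParams(model_id, {"c": c, "b": b, "d": onsets})
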