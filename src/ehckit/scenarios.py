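"""The 18-scenario simulation battery.

A standard parameter set (one-parameter-at-a-time variations of which define
scenarios S1–S18) is crossed with three-level cases for the Michaelis
constant ``km`` (cases I–IV) and the biliary transfer rate ``kehc`` (cases
A–E).  Each scenario is assigned one km-case and one kehc-case, giving
3 x 3 = 9 runs per scenario and 162 runs in total.  The kehc levels of each
case are chosen so that, under the paired scenario's elimination constants,
the theoretical maximum EHC fraction is approximately 40 / 60 / 80 %.

Per-scenario mean and SD of AUC0-inf are summarized and each scenario is
compared against the unmodified standard model (S7) with a Welch two-sample
t-test on the nine AUC values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .pk_core import PKParameters, ehc_max
from .simulator import SimulationResult, SolverConfig, simulate

__all__ = [
    "KM_CASES",
    "KEHC_CASES",
    "EHC_LEVEL_LABELS",
    "ScenarioSpec",
    "BatteryResult",
    "standard_params",
    "scenario_spec",
    "scenario_ids",
    "build_params",
    "battery_plan",
    "run_battery",
    "compare_to_standard",
]

#: km levels (mg/L) per case, ordered low -> high EHC effect.
KM_CASES: dict[str, tuple[float, float, float]] = {
    "I": (10.0, 0.1, 0.001),
    "II": (1.0, 0.01, 0.0001),
    "III": (100.0, 1.0, 0.01),
    "IV": (100.0, 10.0, 1.0),
}

#: kehc levels (1/h) per case, ordered low -> high EHC level (~40/60/80 %).
KEHC_CASES: dict[str, tuple[float, float, float]] = {
    "A": (0.0666, 0.15, 0.4),
    "B": (0.3333, 0.75, 2.0),
    "C": (0.0133, 0.03, 0.08),
    "D": (0.7333, 1.65, 4.4),
    "E": (0.1333, 0.36, 0.88),
}

EHC_LEVEL_LABELS = ("40%", "60%", "80%")

#: Default dose (mg).  The compartmental model is linear in dose except for
#: the Michaelis-Menten term, so absolute AUC values scale with this choice.
DEFAULT_DOSE = 10.0

DEFAULT_HORIZON = 96.0
#: Scenarios whose drug persists well past 96 h get a longer horizon.
LONG_HORIZON = 240.0
_LONG_SCENARIOS = ("S4", "S15")


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: parameter override(s) plus its km / kehc case pairing."""

    id: str
    overrides: Mapping[str, float]
    km_case: str
    kehc_case: str
    description: str
    horizon: float = DEFAULT_HORIZON


_SCENARIO_ROWS = (
    ("S1", {"ka": 1.5}, "I", "A", "Rapid absorption in the intestinal compartment"),
    ("S2", {"ka": 0.3}, "I", "A", "Slow absorption in the intestinal compartment"),
    ("S3", {"krel": 0.5}, "II", "B", "Rapid renal elimination from central compartment"),
    ("S4", {"krel": 0.02}, "III", "C", "Slow renal elimination from central compartment"),
    ("S5", {"kgel": 0.5}, "I", "A", "Rapid elimination from intestinal compartment"),
    ("S6", {"kgel": 0.02}, "I", "A", "Slow elimination from intestinal compartment"),
    ("S7", {"tlag": 0.0}, "I", "A", "Drug release without delay time"),
    ("S8", {"tlag": 2.0}, "I", "A", "Time-delayed drug release"),
    ("S9", {"a": 0.5}, "I", "A", "Parabolic drug release"),
    ("S10", {"a": 2.0}, "I", "A", "Sigmoidal drug release"),
    ("S11", {"kmax": 6.0}, "I", "A", "Rapid gallbladder emptying"),
    ("S12", {"kmax": 1.5}, "I", "A", "Slow gallbladder emptying"),
    ("S13", {"b": 600.0}, "I", "A", "Short gallbladder emptying duration"),
    ("S14", {"b": 100.0}, "I", "A", "Long gallbladder emptying duration"),
    ("S15", {"k12": 1.0, "k21": 0.1}, "II", "D",
     "Fast peripheral distribution with slow central return"),
    ("S16", {"k12": 0.1, "k21": 1.0}, "I", "E",
     "Slow peripheral distribution with fast central return"),
    ("S17", {"vmax": 1.0}, "IV", "A", "Broad first pass elimination"),
    ("S18", {"vmax": 0.02}, "I", "A", "Reduced first pass removal"),
)

SCENARIOS: dict[str, ScenarioSpec] = {
    sid: ScenarioSpec(
        id=sid, overrides=dict(ov), km_case=kmc, kehc_case=kec,
        description=desc,
        horizon=LONG_HORIZON if sid in _LONG_SCENARIOS else DEFAULT_HORIZON,
    )
    for sid, ov, kmc, kec, desc in _SCENARIO_ROWS
}


def scenario_ids() -> tuple[str, ...]:
    return tuple(SCENARIOS)


def standard_params(
    dose: float = DEFAULT_DOSE,
    horizon: float = DEFAULT_HORIZON,
    km: float = KM_CASES["I"][1],
    kehc: float = KEHC_CASES["A"][1],
) -> PKParameters:
    """Standard parameter set.

    ka=0.9, krel=0.1, kgel=0.1, kd=0.5, tlag=0, a=1, kmax=3.0, b=300,
    meals at 5/11/17 h, k12=k21=0, vmax=0.1 — with km and kehc defaulting to
    the middle levels of their default cases (I and A).
    """
    base = PKParameters()  # pk_core defaults ARE the standard values
    return base.with_overrides({"dose": dose, "horizon": horizon, "km": km, "kehc": kehc})


def scenario_spec(scenario_id: str) -> ScenarioSpec:
    """Look up a scenario by id (S1..S18)."""
    try:
        return SCENARIOS[scenario_id]
    except KeyError:
        raise KeyError(f"unknown scenario {scenario_id!r}; expected S1..S18") from None


def build_params(
    spec: ScenarioSpec | str,
    km_level: int = 1,
    kehc_level: int = 1,
    dose: float = DEFAULT_DOSE,
) -> PKParameters:
    """Concrete parameters for one battery run (level indices 0/1/2, low->high)."""
    if isinstance(spec, str):
        spec = scenario_spec(spec)
    if km_level not in (0, 1, 2) or kehc_level not in (0, 1, 2):
        raise ValidationError("km_level and kehc_level must be 0, 1 or 2")
    overrides = dict(spec.overrides)
    overrides["km"] = KM_CASES[spec.km_case][km_level]
    overrides["kehc"] = KEHC_CASES[spec.kehc_case][kehc_level]
    overrides["dose"] = dose
    overrides["horizon"] = spec.horizon
    return standard_params().with_overrides(overrides)


def battery_plan(
    scenarios: Iterable[str] | None = None, dose: float = DEFAULT_DOSE
) -> list[dict]:
    """Enumerate every battery run (km level outer, kehc level inner).

    The full plan over the 18 scenarios has 162 entries.
    """
    ids = tuple(scenarios) if scenarios is not None else scenario_ids()
    plan = []
    for sid in ids:
        spec = scenario_spec(sid)
        for i_km in range(3):
            for i_ehc in range(3):
                plan.append({
                    "run_id": f"{sid}-km{i_km}-ehc{i_ehc}",
                    "scenario": sid,
                    "km_case": spec.km_case,
                    "km_level": i_km,
                    "km": KM_CASES[spec.km_case][i_km],
                    "kehc_case": spec.kehc_case,
                    "kehc_level": i_ehc,
                    "kehc": KEHC_CASES[spec.kehc_case][i_ehc],
                    "dose": dose,
                    "horizon": spec.horizon,
                })
    return plan


@dataclass
class BatteryResult:
    """Per-run AUC records and per-scenario summary of a battery."""

    runs: pd.DataFrame
    summary: pd.DataFrame
    dose: float

    def scenario_aucs(self, scenario_id: str) -> np.ndarray:
        return self.runs.loc[self.runs["scenario"] == scenario_id, "auc_inf"].to_numpy()


def run_battery(
    cfg: SolverConfig | None = None,
    scenarios: Iterable[str] | None = None,
    dose: float = DEFAULT_DOSE,
) -> BatteryResult:
    """Simulate every (scenario, km level, kehc level) combination.

    Deterministic given the configuration: the model has no random inputs.
    Integration failures are re-raised with the offending run id attached.
    """
    cfg = cfg or SolverConfig()
    records = []
    for entry in battery_plan(scenarios, dose):
        p = build_params(entry["scenario"], entry["km_level"], entry["kehc_level"], dose)
        try:
            res = simulate(p, cfg)
        except Exception as exc:  # attach run identity to solver diagnostics
            raise type(exc)(f"{entry['run_id']}: {exc}") from exc
        spec = scenario_spec(entry["scenario"])
        records.append({
            **entry,
            "ehcmax_pct": ehc_max(p.kehc, p.krel, p.k12),
            "auc_inf": res.auc_inf,
        })
    runs = pd.DataFrame.from_records(records)
    summary = (
        runs.groupby("scenario", sort=False)["auc_inf"]
        .agg(mean_auc="mean", sd_auc=lambda x: x.std(ddof=1), n_runs="count")
        .reset_index()
    )
    return BatteryResult(runs=runs, summary=summary, dose=dose)


def compare_to_standard(b: BatteryResult, reference: str = "S7", alpha: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test of each scenario's AUCs against the reference.

    Identical samples short-circuit to p = 1 (zero variance would otherwise
    make the statistic undefined).  Returns one row per scenario with the
    p-value and a significance flag at ``alpha``.
    """
    ref = b.scenario_aucs(reference)
    if ref.size == 0:
        raise ValidationError(f"reference scenario {reference!r} not in battery")
    rows = []
    for sid in b.runs["scenario"].unique():
        x = b.scenario_aucs(sid)
        if x.size == ref.size and np.allclose(np.sort(x), np.sort(ref), rtol=0, atol=0):
            p_val = 1.0
        else:
            p_val = float(stats.ttest_ind(x, ref, equal_var=False).pvalue)
        rows.append({"scenario": sid, "p_value": p_val, "significant": p_val < alpha})
    return pd.DataFrame(rows)
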