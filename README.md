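# ehckit

Simulation and AUC estimation for drugs undergoing **enterohepatic
circulation (EHC)**.

Drugs secreted from the liver into bile are stored in the gallbladder,
discharged into the duodenum at meals, and reabsorbed — so their plasma
concentration–time curves show secondary peaks after every meal. These
multi-peak profiles break the assumptions behind routine exposure
estimation: the trapezoidal AUC0–∞ depends heavily on whether the sampling
schedule catches the peaks, which matters for bioequivalence studies and
for therapeutic drug monitoring (TDM) of narrow-window drugs such as
mycophenolic acid. `ehckit` is for pharmacometricians who want to study
that problem quantitatively: it simulates EHC kinetics mechanistically and
estimates AUC0–∞ from sparse samples with closed-form empirical models.

## What it does

**Mechanistic simulator.** A five-compartment ODE model — central (DC),
peripheral (DP), intestinal (DG), undissolved solid dose (DS) and biliary
(DB) amounts, unit-volume convention — with

* Weibull dissolution of the solid dose:
  `fdis(t) = 1 − exp(−(kd·(t−tlag))^a)`,
* meal-triggered gallbladder emptying,
  `kgem(t) = kmax·Σᵢ exp(−b·sin²(π(t−cᵢ)/24))`, a 24 h-periodic pulse train
  centred on the meal times cᵢ,
* Michaelis–Menten biotransformation `vbio = vmax·DC/(km + DC)`,
* first-order absorption (ka), renal (krel) and fecal (kgel) elimination,
  peripheral exchange (k12/k21) and biliary transfer (kehc).

The fraction of central-compartment drug undergoing EHC,
`EHC% = 100·kehc/(kehc + krel + k12 + vbio)`, fluctuates between the
closed-form bounds `EHCmin%` (saturating concentrations) and `EHCmax%`
(vanishing concentrations). The reference exposure AUC0–∞ is computed by
integrating to effective infinity plus a log-linear terminal tail.

**Scenario battery.** Eighteen one-parameter-at-a-time scenarios (S1–S18)
crossed with three-level cases for km (I–IV) and kehc (A–E), 162 runs in
total, with per-scenario AUC summaries and Welch tests against the
unmodified standard model (S7).

**Empirical estimators.** Six closed-form concentration models, all with
exact analytic AUC0–∞: a biexponential reference (M0), a gamma term plus
Gaussians (M1), a sum of gamma-CDF rises under an exponential envelope
(M2, the generalized double-gamma model used in mycophenolate TDM),
switched saturating rises (M3), tanh rises under a shared elimination
envelope (M4), and M4 extended with day-repeating replicate peaks whose
heights continue the observed peak-height envelope (M5). Fitting is
bounded trust-region least squares behind a scikit-learn style estimator,
with AICc model selection
(`AICc = n·ln(SSE/(n−k)) + 2k + 2k(k+1)/(n−k−1)`).

**Sampling toolkit.** The meal-based and conventional 17-point schedules
and five nested TDM schemes (5–9 samples), trapezoidal AUC with optional
λz tail, and a seeded measurement-noise generator for fixtures.

## Worked example

Simulate the standard drug at the 80 % EHC level, sample it on the
meal-based schedule, and estimate AUC0–∞ with the replicate-peak model M5:

```python
import numpy as np
from ehckit import (standard_params, simulate, scheme, extract_samples,
                    MultiPeakRegressor, trapezoid_auc, ehc_max)

params = standard_params(km=10.0, kehc=0.4)       # case-A high level
print(ehc_max(params.kehc, params.krel, params.k12))  # 80.0

result = simulate(params)
print(round(result.auc_inf, 2))                   # 60.56  (mg*h/L)

profile = extract_samples(result, scheme("meal_based"))
reg = MultiPeakRegressor(model="M5", n_peaks=4, ref_auc=result.auc_inf)
reg.fit(profile.times, profile.concentrations)
print(round(reg.auc_inf_, 2), round(reg.accuracy_pct_, 1))  # 49.75 82.2
print(round(trapezoid_auc(profile, extrapolate=True), 2))   # 61.38
```

Reading the numbers: the theoretical EHC ceiling at `kehc = 0.4/h` with
`krel = 0.1/h` is 80 %; the simulated reference exposure is 60.56 mg·h/L.
From the 17 meal-based samples the fitted M5 curve integrates to
49.75 mg·h/L (82.2 % of the reference — M5's replicate envelope decays
faster than the true day-over-day elimination, see `docs/methods.md`),
while the trapezoid with a terminal tail gives 61.38 mg·h/L on this
densely sampled schedule.

The same workflow from the shell:

```bash
ehckit pipeline --out-dir pipe --models M0,M4,M5 --peaks 4
# selected M4 (AICc -7.30, accuracy 103.8%) -> pipe/report.json
ehckit battery --scenarios S1,S7 --out-dir battery
ehckit simulate --scenario S4 --out-dir s4 && ehckit sample --traj s4/trajectory.csv --scheme tdm5 --out s4/tdm5.csv
```

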