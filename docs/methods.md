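# Methods

## The compartmental model

Five state variables track drug amount (mg) in: central plasma (DC),
peripheral tissue (DP), intestinal lumen (DG), undissolved solid dose (DS)
and bile (DB). All compartments use a unit-volume convention (amounts in an
apparent 1 L volume), so amounts and concentrations coincide numerically
and the Michaelis–Menten rate (mg/h) can be summed with first-order terms
(1/h) without explicit volumes. The dynamics are

```
dDC/dt = ka·DG + k21·DP − (k12 + kehc + krel)·DC − vbio(DC)
dDP/dt = k12·DC − k21·DP
dDG/dt = fdis(t)·DS + kgem(t)·DB − (ka + kgel)·DG
dDS/dt = −fdis(t)·DS
dDB/dt = kehc·DC − kgem(t)·DB
```

with three non-constant coefficients:

* **Dissolution** `fdis(t) = 1 − exp(−(kd·(t − tlag))^a)` for `t > tlag`,
  0 otherwise. The exponent is written with `kd` scaling *time* so it stays
  dimensionless for every shape `a`; the alternative `kd·(t−tlag)^a`
  convention is available (`WeibullDissolution(scaled_time=False)`), and the
  two coincide at `a = 1`, the standard value. Below the lag the formula
  would produce complex values for non-integer `a`; returning exactly zero
  implements the meaning of a dissolution delay. Note that the cumulative
  dissolved *fraction* multiplies DS as a time-varying first-order
  coefficient — this is the literal reading of the model equations; a
  hazard-rate reading would be an alternative but is not what the equations
  state.
* **Gallbladder emptying** `kgem(t) = kmax·Σᵢ exp(−b·sin²(π(t−cᵢ)/24))`,
  a smooth 24 h-periodic pulse train centred on the meal times cᵢ. At the
  standard sharpness `b = 300` each pulse has a half-width of roughly
  ±0.3 h and the inter-pulse level is below 1e−100·kmax, which realizes the
  assumption that the gallbladder only empties at meals; periodicity makes
  the meals repeat identically every day.
* **Biotransformation** `vbio = vmax·DC/(km + DC)`: saturable hepatic
  elimination. Small `km` (high enzyme affinity) makes biotransformation
  compete strongly with biliary transfer at low concentrations.

The share of central drug leaving through the biliary route,
`EHC%(t) = 100·kehc/(kehc + krel + k12 + vbio(DC))`, is bounded by the
closed forms `EHCmax% = 100·kehc/(kehc + krel + k12)` (DC → 0) and
`EHCmin% = 100·kehc/(kehc + krel + k12 + vmax)` (saturating DC). The
simulator records the EHC% trace and asserts these bounds. The `vbio` term
in EHC% is used as the rate value itself (mg/h alongside 1/h constants, the
unit-volume convention again); this is the only reading under which the
printed saturation limit EHCmin% is actually attained at high
concentrations.

### Standard parameters

| parameter | value | units | meaning |
|---|---|---|---|
| ka | 0.9 | 1/h | intestinal absorption |
| krel | 0.1 | 1/h | renal elimination |
| kgel | 0.1 | 1/h | fecal elimination |
| kd, tlag, a | 0.5, 0, 1 | 1/h, h, – | Weibull dissolution |
| kmax, b | 3.0, 300 | 1/h, – | gallbladder pulse height / sharpness |
| cᵢ | 5, 11, 17 | h | meal times |
| k12, k21 | 0, 0 | 1/h | peripheral exchange |
| vmax | 0.1 | mg/h | max biotransformation rate |
| km | case level | mg/L | Michaelis constant |
| kehc | case level | 1/h | biliary transfer |

km and kehc are taken from three-level cases (I–IV: {10, 0.1, 0.001},
{1, 0.01, 1e−4}, {100, 1, 0.01}, {100, 10, 1} mg/L; A–E: {0.0666, 0.15,
0.4}, {0.3333, 0.75, 2.0}, {0.0133, 0.03, 0.08}, {0.7333, 1.65, 4.4},
{0.1333, 0.36, 0.88} 1/h). The kehc levels of each case reproduce
EHCmax ≈ 40/60/80 % under the elimination constants of the scenario the
case is paired with; this is exact for cases A–D and approximate for case
E, whose middle and high levels give 64.3 % and 81.5 % under S16's
k12 = 0.1 — the levels are encoded as printed and the discrepancy is
accepted. The tabulated label of the lowest row is taken as the 40 % level,
the value its kehc entries actually produce.

**Dose and horizon.** No dose or compartment volume accompanies the
published parameter set, so absolute exposures are defined only up to that
choice; the package default is 10 mg (configurable), a mid-range oral dose
that keeps peak plasma levels at a few mg/L. Scenarios run to 96 h, except
the slow-elimination (S4) and distribution (S15) scenarios, which persist
longer and run to 240 h. All absolute AUC values in this package are
internally consistent but not comparable to any externally tabulated means.

## Numerics

* **Integration**: `scipy.integrate.solve_ivp` (LSODA), `rtol 1e−8`,
  `atol 1e−10`, and `max_step = 0.05 h` so the ±0.3 h bile pulses are never
  stepped over (the dominant accuracy constraint; without the cap the
  solver skips whole pulses and the secondary peaks vanish).
* **Mass audit**: the state is augmented with running integrals of plasma
  AUC and the renal/fecal/biotransformed eliminations, so
  `dose − Σstates − Σeliminated` measures pure solver error; it stays below
  1e−6 relative (typically ~1e−12) on randomized parameter sets.
* **Reference AUC0–∞**: integration continues past the horizon until the
  drug remaining in the body falls below 1e−6 of the dose (or a 2000 h
  cutoff), then adds a `C_last/λz` tail. λz is fitted log-linearly on
  *total remaining mass* over its last decade rather than on plasma
  concentration: mass is monotone and shares the terminal eigenvalue, while
  the plasma trace oscillates with every bile pulse. A fitted rate at
  rounding level (≤ 1e−8/h) is reported as a non-decaying system rather
  than extrapolated.
* **Non-negativity**: sub-tolerance negative excursions of DC are clipped
  to zero before the Michaelis–Menten term (undefined for DC < −km).

## Empirical models

Layouts (n = number of peaks; shared elimination parameter first):

| model | parameters | count | AUC0–∞ |
|---|---|---|---|
| M0 | a, b, c (c > b) | 3 | a(1/b − 1/c) |
| M1 | a, b, c + (dᵢ, fᵢ, gᵢ) per secondary peak | 3n | aΓ(c+1)/b^{c+1} + Σ dᵢgᵢ(√π/2)(1 + erf(fᵢ/gᵢ)) |
| M2 | a + (bᵢ, cᵢ, dᵢ) per peak | 1+3n | Σ (bᵢ/a)(cᵢ/(a+cᵢ))^{dᵢ} |
| M3 | a + (bᵢ, cᵢ, dᵢ) per peak | 1+3n | Σ bᵢe^{−acᵢ}[cᵢ/a + 1/a² − cᵢ/(a+dᵢ) − 1/(a+dᵢ)²] |
| M4 | c + (bᵢ, dᵢ) per peak | 1+2n | (π/2 − 1)/c · Σ bᵢe^{−cdᵢ} |
| M5 | as M4 | 1+2n | M4 + geometric replicate series |

Every closed form is cross-checked against an independent day-by-day
adaptive-quadrature oracle to 1e−6 relative in the test suite. The tanh
factor of M4 uses `∫₀^∞ e^(−x) tanh(x) dx = π/2 − 1 ≈ 0.5708` (substitute
`s = e^(−x)`: the integral becomes `1 − 2∫₀¹ s²/(1+s²) ds = π/2 − 1`).

Interpretive choices, each taken for dimensional consistency and the
published parameter counts:

* **M2** is implemented as `e^{−at} Σ bᵢ·P(dᵢ, cᵢt)` with `P` the
  regularized lower incomplete gamma — a gamma-CDF rise with shape dᵢ and
  *rate* cᵢ. The as-printed integrand would make bᵢ and cᵢ enter only as a
  product (one parameter too few); that literal reading remains available
  via `m2_literal=True`.
* **M3**'s exponent is `−dᵢ(t − cᵢ)` with dᵢ a rate (1/h).
* **M1** is laid out as one gamma-type absorption term plus one Gaussian
  per *secondary* peak: 3n parameters. The published count for M1 (2 + 3n)
  cannot be reconciled with any natural reading of its formula; both counts
  are exposed (`structural_param_count` vs `param_count`) and M1 is
  excluded from count-based reference checks. AICc uses the structural
  (actually fitted) count.
* **M5** replicates every first-day peak at +24 h, +48 h, …, with heights
  continuing the exponential envelope traced by the observed first and last
  peak heights `hᵢ = bᵢe^{−cdᵢ}`: the envelope rate is
  `λ = ln(h₁/hₙ)/(dₙ − d₁)` and the day-j replicate of peak i has height
  `hᵢ·e^{−λ(24j + dᵢ − d₁)}`. The replicate AUC is a geometric series with
  ratio `e^{−24λ}`; it converges iff the envelope decays (λ > 0), otherwise
  a divergence error is raised. This exponent is a reconstruction: it is
  the only reading that is dimensionally consistent, matches the stated
  intent (peaks repeating "with an intensity and at a time like the first
  day") and yields a finite AUC. With a single peak the envelope is
  undefined; the λ → c limit is used (replicates follow the elimination
  envelope).

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`, TRF)
on an unweighted SSE, wrapped in a scikit-learn estimator
(`MultiPeakRegressor`). Design choices:

* **Starting values** are deterministic and data-driven: peak onsets from
  prominence-ranked local maxima (missing onsets spread over the sampled
  span), the elimination rate screened over a small grid mixing the
  terminal log-linear slope with the steepest observed point-to-point
  decay, and amplitudes from a non-negative linear least-squares
  subproblem — every model is linear in its amplitudes once the shape
  parameters are fixed, so the best candidate is chosen by its NNLS
  residual before any nonlinear iteration.
* **Multi-start**: 5 restarts by default (first from the deterministic
  guess, the rest log-normally jittered, seeded); best SSE wins.
* **Onset ordering** is enforced structurally (first onset + positive
  increments), which removes permutation degeneracy. Onsets beyond the
  last sample time are discouraged by a soft penalty residual: the data
  cannot see them, but they would drive the extrapolated AUC arbitrarily.
* **M5 envelope restriction**: the last amplitude is fitted as the
  envelope ratio ρ = hₙ/h₁ ∈ [0, 0.995], so the replicate series always
  converges. Exactly-determined limited-sampling fits otherwise routinely
  pick a growing envelope and report infinite AUC; this is the package's
  concrete form of the per-fit coefficient restrictions that practical NLR
  of these models is known to need.
* **Metrics**: `rmse = sqrt(SSE/(n−k))` and
  `adj R² = 1 − (SSE/(n−k))/(SST/(n−1))`, the degrees-of-freedom forms
  used by common curve-fitting tools; AICc defaults to the
  `n·ln(SSE/(n−k))` form (the `n·ln(SSE/n)` textbook variant is available
  via `aicc_form="standard"`; both are monotone in SSE). Ranking breaks
  AICc ties toward fewer parameters, then higher adjusted R².

### Identifiability

On 17-point profiles, M0, M1, M4 and M5 refit their own noise-free output
to ~1e−8 relative in every parameter. M2 and M3 do **not**: both admit
impostor parameter sets with SSE ≈ 1e−11 and parameters far from truth
(M2's shape/rate pairs trade off almost freely; M3's onset and rise rate
compensate each other). This is structural, not an optimizer failure, and
consistent with practical experience that regressions of the double-gamma
family are hard to reproduce. The estimable quantity survives: the fitted
curves and their closed-form AUCs agree with truth to ~1e−5 (M2) and a few
percent (M3). Tests therefore assert parameter recovery for the
identifiable four and functional (curve + AUC) recovery for M2/M3.

## The synthetic-data generator

Test fixtures are generated, never stored: simulated profiles come from
the ODE model at the tabulated parameter levels, synthetic multi-peak
profiles from known M4/M5 parameter vectors (a 4-peak sawtooth with peak
heights 1.2/0.8/0.6/0.45 mg/L at 0.5/5.5/11.5/17.5 h under c = 0.35/h —
amplitudes chosen so the peak-height envelope decays, as real EHC profiles
do), and measurement error from a seeded noise model
`c′ = max(0, c(1 + ε) + η)` with proportional CV 10 % by default — a
typical bioanalytical assay precision. What this emulates: sampling-time
geometry, peak coverage, assay noise. What it does not: between-subject
variability, absorption-time jitter between days, meal-time deviations,
below-quantification censoring. Passing tests therefore speak to the
estimators' numerical behaviour under the stated kinetic model, not to
clinical performance on real profiles.

## Known limitations

* **M5 envelope vs terminal decay**: M5's replicate envelope is, by
  construction, the intra-day first-to-last peak-height decay. The
  absorption peak inflates h₁, so the fitted envelope (λ ≈ 0.06–0.13/h in
  the standard scenarios) decays faster than the simulator's day-over-day
  terminal rate (λz ≈ 0.038–0.074/h), and meal-based M5 estimates
  under-predict AUC0–∞ by roughly 8–18 % at high EHC levels. The
  model-free trapezoid with λz tail does not share this bias.
* **Under-determined sparse fits**: conventional sampling observes at most
  two of the four peaks, so a 4-peak M5 fit has flat directions; its
  extrapolated AUC is unstable across multi-start configurations and noise
  replicates. The meal-based vs conventional comparison is therefore
  summarized by median accuracy deviation over ten seeded noise
  replicates. TDM1 (five rising samples, no decay information) leaves even
  the elimination rate unidentified and its AUC estimates are not
  meaningful; tests assert the scheme-geometry peak-coverage rule
  (TDM1/2 → 2, TDM3/4 → 3, TDM5 → 4 covered peaks) and that M5 beats the
  truncated trapezoid on TDM2–TDM5.
* **Battery statistics**: the per-scenario comparison against the standard
  model uses a two-sided Welch t-test on 9-vs-9 AUC values (the variance
  differs strongly across scenarios); identical samples short-circuit to
  p = 1. The flagged set depends on the dose convention and is reported,
  not asserted, beyond ordering sanity.
* Single-dose kinetics only; no event-based (switch-type) gallbladder
  models, no hepatic sub-compartment, no population-level (mixed-effect)
  extensions, no BLQ handling.

## Problem sizes

The test suite simulates a subset battery (8 scenarios × 9 runs), 100
randomized parameter sets for the mass-balance audit at a 48 h horizon,
100 noise replicates for the accuracy Monte Carlo, and 10 noise replicates
per scheme for the sampling comparison — sizes chosen so the full suite
exercises every pathway in a couple of minutes on one core. The full
162-run battery runs in well under a minute via `ehckit battery`.
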