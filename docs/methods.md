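# Methods

## Model structure and assumptions

The kinetic model has three physiological compartments plus a gut
absorption pool.  Oral intake enters the gut and is absorbed at rate `ka`
(1/h); a fraction `bioAv` of the absorbed flow reaches the central
compartment and the remainder leaves through an explicit unabsorbed sink
(so mass balance is checkable).  The central compartment (volume
`Vc = VCC·BW`) exchanges with a deep tissue compartment by first-order
rates `k12`/`k21`; the deep pool is tracked in amounts, so its volume —
which does not affect serum dynamics — never enters the equations.  Renal
elimination runs through a filtrate compartment of volume
`Vfil = VfilC·BW`: the free fraction (`Free`) of central chemical is
filtered at flow `Qfil = QfilC·QCC·BW^0.74`, and from the filtrate the
chemical either leaves in urine (`Qfil·C_fil`) or is resorbed back to
serum by a saturable Michaelis–Menten carrier with maximum rate
`Tm = Tmc·BW` and affinity `Kt`.

Assumptions worth stating explicitly:

- the serum observable is the **total** central concentration
  `A_prim/Vc` (PK datasets report total serum, not free);
- `Free` multiplies only the filtration flux, not the deep-tissue
  exchange;
- physiology is constant: no growth, no pregnancy/lactation compartments,
  no age-varying filtration;
- dosing: IV boluses increment `A_prim`, oral boluses increment `A_gut`,
  and continuous intake enters the gut as a rate (mg/h).

Default parameter values ship as packaged YAML fixtures per chemical and
species.  Units follow one convention everywhere: amounts mg, volumes L,
flows L/h, concentrations mg/L (≡ µg/mL); µg/L (ppb) appears only at I/O
boundaries (biomonitoring tables).

| parameter | meaning | units |
|---|---|---|
| `BW` | body weight | kg |
| `QCC` | cardiac output coefficient | L/h/kg^0.74 |
| `QfilC` | fraction of cardiac output filtered | – |
| `VfilC` | filtrate volume coefficient | L/kg |
| `bioAv` | oral bioavailability | – |
| `VCC` | central volume coefficient | L/kg |
| `Tmc` | max resorption rate coefficient | mg/h/kg |
| `Kt` | resorption affinity | mg/L |
| `Free` | free fraction in serum | – |
| `k12`, `k21` | central↔deep exchange | 1/h |
| `ka` | gut absorption rate | 1/h |

## Numerical integration

`Vfil` is tiny (4×10⁻⁴ L/kg), which makes the filtrate equation relax on
a µs–ms timescale against serum dynamics of hours — the system is stiff.
Two integrators are provided and cross-checked in the tests:

- **Reference (`method="stiff"`, default):** the full system under BDF with an
  analytic Jacobian, restarted at every bolus event.  (LSODA was
  rejected: its ODEPACK step control can stall in an infinite loop at
  tight absolute tolerances when a fast-decaying component reaches
  zero.)  Components decayed below 10⁻³⁰ of the state norm are zeroed
  between segments.
- **Fast path (`method="qss"`):** the filtrate equation is replaced by its
  quasi-steady-state solution (a scalar quadratic in `C_fil`, solved in
  the cancellation-free conjugate form), after which the only remaining
  stiffness sits in the *constant linear* part of the system (`ka` and the
  deep exchange).  That part is propagated exactly through its closed-form
  eigendecomposition, and only the slow resorption loss and the intake
  forcing are stepped explicitly (adaptive second-order exponential
  integrator, ETD2RK).  The eigenbasis is written out analytically so the
  urine/unabsorbed quadratures stay exactly decoupled from the dynamic
  states; the error test adds a floor of 10⁻¹³ times the current dynamic
  state norm so that roundoff leaked into exactly-zero components cannot
  stall the step controller.  The matrix is defective only at
  `ka = k12 + k21`, where `ka` is nudged by one part in 10⁸ (far below any
  parameter's precision).

The fast path agrees with the reference to ~10⁻⁸ relative on 26-week
repeated-dose schedules and ~10⁻⁶ on decade-long washouts, at roughly a
thousandth of the cost; calibration and MCMC use it (at `rtol=10⁻⁶`,
noise-dominated settings), all reference dosimetry uses closed forms, and
the stiff solver remains the oracle in the test suite.  Default
tolerances are `rtol=10⁻⁸`, `atol=10⁻¹⁰`; trajectories are clamped to
zero when a component undershoots by less than 10³·atol.

Life-course (biomonitoring) simulations default to an exact
piecewise-exponential solution of the linearized system: at survey-scale
intakes (ng/kg/day) the filtrate concentration is 3–4 orders of magnitude
below `Kt`, so the kinetics are linear; each log-linear intake segment is
an exponential forcing with a closed-form particular solution.  An
automatic validity check (peak `C_fil` above 1% of `Kt`) switches to the
full ODE, and step-mode trajectories always use the ODE path.

## Steady-state dosimetry

Forward and reverse dosimetry are closed-form (see README) and exact
inverses of each other (round-trip error ≤10⁻¹⁰ enforced in tests).  The
human-equivalent dose convention is the **administered** (pre-
bioavailability) dose: `dose = 24·Qfil·C_fil/(bioAv·BW)`.  This
convention reproduces the published PFOA reverse-dosimetry table to
within printed precision; the corresponding PFOS rows reproduce only to
~10–20%, consistent with the 2-significant-figure rounding of the printed
PFOS parameters (one printed PFOS row pair is internally inconsistent:
sub-saturating doses scale proportionally with the serum POD, yet the
printed doses for the 0.009 and 0.010 mg/L PODs differ by just 1.4%).
Clearance in the sub-saturating limit is
`CL = Qfil²·Free/(Qfil + Tm/Kt)` (L/h; reported as mL/kg/day), invariant
under joint scaling of `Tm` and `Kt` and bounded above by `Qfil·Free`.

## Half-life and human scaling

Animal-to-human scaling keeps all chemical-specific constants, replaces
the physiology by a 70 kg adult with `QCC = 12.5 L/h/kg^0.74`, and
recalibrates `Tmc` so the model's serum half-life matches the human
half-life reported from exposure studies (3.4 y PFOS, 2.7 y PFOA, 5.3 y
PFHxS).  Because the half-life is strictly increasing in `Tmc`, the
calibration is a Brent root search on log₁₀ `Tmc`; targets below the
`Tm=0` floor raise an explicit infeasibility error.

Three half-life operationalizations are implemented:

- `terminal-slope` (default): regress log₁₀ serum on time over the final
  decade of a washout simulation after a sub-saturating IV bolus
  (10⁻⁶ mg/kg); warns when the tail is not log-linear (R² < 0.999).
- `eigenvalue`: ln 2 over the smallest-magnitude eigenvalue of the
  linearized system; agrees with the terminal slope to ≲0.1% and serves
  as a cross-check.
- `one-compartment`: `ln2·Vc/CL`, ignoring the deep compartment's
  contribution to the distribution volume.

The published human `Tmc` values are best explained by the
one-compartment convention: it reproduces the printed PFOA value (0.54
mg/h/kg) within 1%, but the printed PFOS (1.07) and PFHxS (0.47) values
back-compute ~15% off under every convention tried — consistent with the
2-significant-figure rounding of the printed parameter tables.  The
discrepancy is documented in the tests rather than forced; the default
remains the terminal-slope estimate because it mirrors how half-lives are
actually measured in human exposure studies, and all self-consistency
guarantees (calibrate → measure round trip, tolerance 10⁻⁴ relative) hold
per convention.

## Calibration

Residuals are taken on log₁₀ concentrations: serum spans orders of
magnitude across dose groups, and raw-scale least squares would be
dominated by the highest-dose group.  MSLE is likewise base-10 by default
(configurable — conventions differ).  Non-positive observations are
excluded with a logged count.

Identifiability is screened with the collinearity index: local
sensitivities `∂log₁₀ pred/∂log₁₀ θ` by central differences (half-step
0.01 log₁₀ units), columns normalized to unit Euclidean norm,
`γ = 1/√λ_min` of the normalized cross-product, threshold 20
(conventional).  On the default study design the free set `{VCC, Tmc,
Kt}` (plus `bioAv` for PFOA-like fits) is identifiable, while adding
`Free` drives γ up several-fold — the reason `Free`, `ka`, `k12`, `k21`
stay at literature values, with a sensitivity analysis
(`fixed_param_sensitivity`) quantifying the robustness of the estimates
to those choices.

Point estimation is trust-region-reflective least squares in
log₁₀-parameter space (bounds ±3 log₁₀ units around the start values,
which default to the packaged reference sets).  The posterior sample uses
the emcee affine-invariant ensemble sampler: flat priors on log₁₀
parameters within bounds, Gaussian error on log₁₀ residuals with the
error variance sampled under a vague inverse-gamma(10⁻³, 10⁻³) prior
(log₁₀σ as an extra dimension).  Walkers start in a tight ball around the
point estimate; the first 30% of steps are discarded as burn-in;
reported diagnostics are the mean acceptance fraction (warned outside
[0.05, 0.6]) and split-chain R̂ per parameter.  Credible intervals are
2.5/97.5 posterior percentiles.  At the default chain length (5000
retained draws) R̂ is typically 1.1–1.3 — adequate for interval coverage,
not for publication-grade tail estimates; run longer chains for those.

## Exposure reconstruction

Population intake is piecewise log-linear in calendar time with knots at
1950/1990/1998/2017, continuous at the knots with slope breaks; the 1950
anchor is 1% of the 1990 level by default (the data begin in 1999, so the
anchor is weakly informed; its main effect is on the oldest cohorts'
pre-peak burden).  A step-jump variant (instantaneous drops at the break
years) is available behind `mode="step"`.  After 2017 the level is
extrapolated as constant.  Respondents are simulated as constant-70-kg
adults from `max(birth year, 1950)`; predictions are only compared for
ages 21–79.  The three levels are fitted by least squares on log₁₀ serum
means, seeded by a crude steady-state inversion of the panel mean; a
single-survey-year design triggers a non-identifiability warning.

## Synthetic data: what it does and does not show

The generators stand in for two datasets that cannot ship: the
proprietary primate PK studies and survey-weighted biomonitoring means.
The default primate design is three daily-oral dose groups (0.03, 0.15,
0.75 mg/kg/day for 26 weeks, sampled through dosing and a washout year)
plus a single 2 mg/kg IV bolus group, six animals each, with
multiplicative lognormal residual error (σ = 0.1 log₁₀ units).  The oral
doses bracket the saturation of resorption — the low dose is linear, the
middle dose sits near the transition, the high dose saturates — because
that bracketing is what makes `Kt` identifiable; the washout-weighted
sampling reflects that the decay back through the transition carries most
of the `Kt` information.  The biomonitoring generator produces
(survey year × age) serum means from a known intake trajectory with
lognormal noise (σ = 0.05 log₁₀ by default) on a 3-survey × 6-age grid.

Passing the recovery and coverage tests therefore shows that the
estimation machinery is correct and well calibrated *under the model*:
i.i.d. multiplicative noise, no inter-animal kinetic variability, no
model misspecification, no survey design effects.  It does not show that
the model fits real monkey or survey data — the published fit-quality
numbers (animal MSLEs of 0.07/0.58/0.17, factor-of-2 coverages of
98%/71%/86%, survey MSLEs of 0.07/0.03) require the original proprietary
datasets and are not reproducible here.  What the tests verify instead is
the metric algebra (a uniform 2× bias gives MSLE = (log₁₀2)² ≈ 0.0906)
and the end-to-end behaviour on data of known provenance.

## Design choices and degenerate inputs

- `Tmc = 0` (no resorption) and `k12 = 0` (no deep exchange) are valid
  degenerate limits, used by the analytic test oracles; all other
  parameters are strictly positive, `bioAv`, `Free`, `QfilC`, `VfilC` ≤ 1.
- Output times coinciding with a bolus report the post-dose state
  (`C(0⁺) = D/Vc` for an IV bolus at t = 0).
- Problem sizes in the statistical suites (20 replicates × 5000 posterior
  draws for coverage; 100 parameter sets for steady-state equivalence;
  5 replicate panels for noisy intake recovery) were chosen as the
  smallest designs whose pass/fail criteria are stable across rerandomized
  seeds.
- Seeds: every stochastic routine takes an explicit seed; generators are
  pure functions of (truth, design, seed).

## Known limitations

- No developmental physiology: children and pregnancy/lactation transfer
  are out of scope, which is why survey comparisons start at age 21.
- One population-average intake trajectory; no demographic stratification
  beyond age × survey year, no survey design weights (the pipeline
  consumes precomputed means).
- The deep compartment is a lumped first-order pool; tissue-specific
  concentrations are outside the model's reach.
- Kinetic parameters are population values: no inter-individual
  variability is propagated into the dosimetry outputs.
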