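# Methods

## Soluble compartment

The CSF is treated as one well-mixed compartment (no volume is modelled;
concentrations are intrinsic). Soluble amyloid-β obeys

    dA/dt = P − k(t) A

with zero-order production P and first-order clearance k(t). The
closed-form segment solution A(t) = (Aᵢ − P/k) e^(−k t) + P/k is exact at
machine precision, so the simulator composes it piecewise between
events (therapy start, each IV dose, discontinuation) rather than
integrating numerically.

Regimes:

* **Untreated** — k = C (natural clearance). From A₀ = 100 pg/mL the
  pool rises with time constant 1/C = 20 months toward P/C =
  3600 pg/mL; at month 120 it has essentially reached it
  (≈3591.3 pg/mL).
* **Intrathecal pseudodelivery** — a continuous added clearance CIT, so
  k = C + CIT = 0.95 month⁻¹ while on therapy; the on-therapy
  steady state is P/(C+CIT) ≈ 189.5 pg/mL, approached with a ≈1-month
  time constant.
* **Intravenous** — doses at t_start + n·τ each multiply the pool by
  (1 − E); between doses k = C. Pre-dose (trough) levels converge
  geometrically, with per-cycle factor (1−E)e^(−Cτ) ≈ 0.38, to
  A_trough = P(1−e^(−Cτ))/(C(1−(1−E)e^(−Cτ))) ≈ 283.4 pg/mL
  (post-dose peak (1−E)·A_trough ≈ 113.4 pg/mL).

### Parameters

| symbol | field | default | units | meaning |
|---|---|---|---|---|
| A₀ | `a0` | 100 | pg/mL | soluble level at model time 0 |
| P | `p_prod` | 180 | pg/mL/month | production rate |
| C | `c_nat` | 0.05 | 1/month | natural clearance |
| CIT | `c_it` | 0.90 | 1/month | intrathecal added clearance |
| E | `e_dose` | 0.60 | – | fractional reduction per IV dose |
| τ | `tau_dose` | 1 | month | IV dosing interval |

Degenerate settings are valid: `c_it = 0` or `e_dose = 0` is a null
therapy, `p_prod = 0` is pure decay.

### Discontinuation and washout

Therapy may stop at `t_stop`. For the intrathecal arm the added
clearance then decays as CIT·e^(−w(t−t_stop)) with an arm-specific
washout rate w, representing antibody remaining in the reservoir and
CSF; `washout_rate="immediate"` removes the effect at once. For the IV
arm, dosing simply ceases (no depot is modelled, so the soluble effect
ends with the last dose); the IV washout rate applies only to the
therapy-induced fibrillar clearance below. During the intrathecal
washout segment the clearance is time-varying; the solution is obtained
from the exact integrating factor K(t) = C t + (CIT/w)(1 − e^(−wt)),
with the remaining production integral ∫e^K evaluated by cumulative
Simpson quadrature on a 0.002-month subgrid. An independent
adaptive-step Runge–Kutta oracle (`ode_reference_solve`, rtol 1e−10)
reproduces the piecewise path to within 1e−6 relative everywhere,
including washout; this dual route is tested on randomized schedules.

## Fibrillar (PET) compartment

Fibrillar burden F(t) is carried directly in centiloids (the
concentration→centiloid scaling is absorbed into the aggregation
coefficient) and driven linearly by the soluble pool:

    dF/dt = k_agg A(t) − (c_f + γ_arm(t)) F,   F(0) = 0

γ_arm is a therapy-induced fibrillar clearance, active while on
therapy and decaying with the arm's washout rate after stop. It is
arm-specific: with a single shared fibrillar clearance the two arms'
on-therapy soluble averages (≈189 vs ≈199 pg/mL) are too close to
separate their PET-negativity times by 18 months — the calibration test
demonstrates this infeasibility directly. Route-dependent plaque
engagement (systemic IV antibody reaches parenchymal plaque; the
CSF-confined route acts mainly through the soluble gradient) is the
mechanistic reading, but the term should be understood as a surrogate.
F is integrated by the same exact integrating-factor construction
(trapezoid cumulative quadrature of ρ(t) = c_f + γ(t) and of
A·e^R on the simulation grid); duplicated pre/post-dose grid points
make the soluble discontinuities exact zero-width intervals. Agreement
with an adaptive ODE solve is ≈3e−7 relative on the default grid.

### Calibration

The four fibrillar parameters plus the two washout rates are fit to
the milestone set

| milestone | target |
|---|---|
| untreated crosses 35 CL upward | month 120 |
| intrathecal falls below 24 CL | month 132 |
| IV falls below 24 CL | month 150 |
| re-positivity delay (intrathecal − IV) after stop-at-negativity | 6 months |

by bounded least squares (scipy trust-region reflective) on the
crossing-time residuals, from 32 Sobol starts sampled log-uniformly
within the bounds (k_agg ∈ [1e−5, 5e−3] CL·mL/pg/month, c_f ∈ [1e−3,
0.1], γ ∈ [1e−4, 0.3], w_it ∈ [0.01, 2], w_iv ∈ [0.01, 5] month⁻¹),
fully reproducible under the documented seed. A milestone whose
crossing never occurs contributes a fixed 1e3-month penalty residual.
Convergence requires every residual within 0.5 month. The shipped
defaults (seed 1) converge with loss ≈1.5e−17 month²:

    k_agg = 1.5858e−4, c_f = 1.0498e−2, γ_it = 2.3359e−2,
    γ_iv = 3.4888e−3, w_it = 0.5912, w_iv = 0.2191

The problem is intentionally over-parameterized (6 parameters, 4
targets), so this is one member of a solution family selected by the
multistart procedure, not an identified parameter set; only the
milestone behaviour, not the individual rate values, carries meaning.
The untreated plateau implied by the fit is k_agg·3600/c_f ≈ 54 CL,
a plausible long-run burden on the centiloid scale.

## Scenario conventions

* **Therapy start** at month 120, the untreated 35-CL crossing
  (symptomatic onset). The first IV dose is given at start, then
  monthly.
* **Percent reduction** is measured against the *pre-treatment* level —
  the untreated trajectory's value at start (≈3591 pg/mL) — not A₀:
  the treated equilibrium (≈189.5 pg/mL) exceeds A₀ = 100 pg/mL, so a
  90% decrease is only meaningful from the elevated symptomatic level.
  Monthly IV metrics use the pre-dose (trough) convention —
  conservative and unambiguous; on that convention the IV arm reaches
  ≈92% at 12 months.
* **Stop rule**: in the discontinuation study each arm stops at its own
  PET-negativity time, and the re-positivity interval is measured from
  each arm's own stop (an absolute-clock reading would conflate the
  18-month head start with the washout difference).
* **Null-delivery semantics**: an arm configured with `c_it = 0`
  (intrathecal) or `e_dose = 0` (IV) delivers no antibody, so the
  scenario layer also zeroes that arm's γ — a null therapy must be
  null for both compartments.
* **Crossing detection** interpolates linearly between grid points and
  returns the first crossing at or after `t_min`; at an instantaneous
  dose jump the crossing time is the jump instant. Ties at the
  threshold resolve in favour of the earlier time. Verified against a
  100× dense-grid scan.

## Numerical choices

* Default grid: dt = 0.01 month, horizon 220 months (320 for
  discontinuation runs, long enough for both arms' re-positivity).
  Test-suite runs use dt = 0.02–0.2 on shorter horizons where only the
  qualitative property is at stake; all milestone assertions use the
  default grid.
* Closed-form vs ODE agreement contract 1e−6 relative; root-finding
  (reaccumulation inversion) tolerance 1e−8 months; calibration
  convergence 0.5 month per milestone.
* Event times are merged into the grid with 1e−9 rounding; therapy
  events outside the horizon are ignored with a logged warning;
  duplicate IV dose times are a configuration error.

## Synthetic cohorts and what the tests show

`generate_virtual_cohort` draws per-subject (P, C, CIT, E) from
lognormal distributions with mean at the defaults and configurable
coefficient of variation (default 0.2), truncated at the 1%/99%
quantiles; `sample_observations` adds multiplicative lognormal noise to
CSF samples (default σ_log = 0.1) and additive Gaussian noise to PET
scans (default σ = 3 CL, clipped at 0 with a logged count). These
magnitudes are package defaults chosen as plausible for lumbar-puncture
assays and amyloid PET — the underlying study is purely hypothetical
and provides no variability or noise estimates. The generator emulates
between-subject kinetic heterogeneity and measurement error only: no
dropout, no limit of detection, no within-subject drift, no covariance
between parameters. Passing recovery tests therefore show the
estimation loop is self-consistent under the model's own assumptions,
not that the model describes real patients.

`recover_params` fits the three identifiable quantities (initial level,
production P, effective clearance k) of the closed-form solution to CSF
observations; C and CIT are not separately identifiable from a single
on-therapy decay, which is why the fit reports the composite k.

## Known limitations

* The fibrillar compartment is a calibrated surrogate, not a validated
  aggregation model; all PET milestones are calibration-consistency
  results, and the independent content of the package lies in the
  soluble kinetics and the machinery around them.
* One-compartment CSF with no brain-ISF exchange, no antibody
  pharmacokinetics (binding, reservoir degradation, redosing), no ARIA,
  tau, or cognition.
* The 6-month re-positivity delay depends on the invented washout
  structure; with identical instantaneous cessation in both arms the
  delay nearly vanishes (shown by a dedicated test).
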