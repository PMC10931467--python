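# Methods

## Model and assumptions

The package implements a deterministic compartmental model in which
social-media addiction propagates through peer contact like an
infectious disease, and depression arises as a downstream state of
addiction. Six compartments (S, E, I₁, I₂, R, Q — susceptible, exposed,
addicted, depressed, recovered, permanent quitters) evolve under the
coupled balance equations given in the README. Standing assumptions:
homogeneous mixing (every individual contacts every other at the same
rate), a closed environment with constant recruitment Λ, rates constant
in time (no seasonality), no age or network structure, and mass-action
incidence ϕχI₁S. Time is treated as dimensionless: none of the model's
conclusions depend on whether the unit is days or weeks, and no data
are fitted.

Bookkeeping identity: summing the six equations leaves
dN/dt = Λ − τN − ρI₂, so the total population is trapped below
max(N(0), Λ/τ). This identity and componentwise positivity from
nonnegative initial states are monitored as runtime invariants of the
integrator and asserted by property tests.

## Parameters

All fourteen parameters are nonnegative; τ must be strictly positive
and ζ, ω, Φ, χ lie in [0, 1]. The packaged `table1_baseline` scenario
pins the three parameters whose sources give only ranges to
τ = 0.05 (low end), α = 0.4 and ϕ = 0.45 (midpoints); both choices are
plain-text YAML and overridable per run. The two reference scenarios
(`case1_r0_lt_1`, `case2_r0_gt_1`) pin every value used in the
corresponding numerical experiments. In the supercritical set the
fraction printed ambiguously as "φ = 0.80142" is interpreted as Φ (the
exposed-to-addicted fraction); under this reading the closed-form
endemic equilibrium reproduces the reported state vector to all four
printed digits, which we take as confirmation.

## Equilibria and R₀

R₀ is evaluated from its closed form; the next-generation-matrix route
(spectral radius of FV⁻¹ on the infected block E, I₁, I₂, R linearised
at the addiction-free equilibrium) is kept as an independent structural
cross-check and agrees to 1e-10 relative over randomized draws.

The endemic equilibrium is **not** transcribed from its multi-page
rational closed forms, which are unverifiable by inspection. Instead we
solve the steady-state system by an exact algebraic cascade: the
susceptible level has the simple closed form
S* = (ς+τ)(τ+α+ψ)/(ςϕχΦ); the E-, I₁-, I₂- and R-balances make I₁, I₂
and R proportional to E; substituting into the S-balance leaves an
equation *linear* in E. The result is closed-form to machine precision
(residual ≲ 1e-16, far below the 1e-10 contract), and Q — which feeds
back into nothing — is recovered last from Q = (βS* + (1−ζ)λR)/τ. A
damped multi-start Newton search on the raw vector field serves as the
independent oracle in the tests: every positive root it finds from 50
random starts coincides with the cascade solution. An equilibrium
component in (−1e-9, 0) is treated as zero; anything more negative
marks the state inadmissible and `eep` returns absent (which is the
outcome whenever R₀ ≤ 1).

The strength (second-order) indicator −2τ²ϕχΛ/(τ+β) is implemented as
the printed scalar only; the derivation in the source material is
internally inconsistent, so nothing beyond the value and its sign
(always nonpositive) is asserted.

## Stability and bifurcation

All eigenvalues are computed numerically from the analytic 6×6 Jacobian
(verified entrywise against central finite differences at 1e-6). The
block-triangular structure guarantees −τ and −(β+τ) in the DFE
spectrum, and these are asserted; a published eigenvalue list containing
−(τ+υ) where the matrix structure implies −(τ+λ) is treated as a typo
and not asserted. Verdicts use a marginality tolerance of 1e-9 on the
largest real part (configurable): stable below −tol, unstable above
+tol, marginal between.

For the bifurcation coefficients the contact rate is set to its
critical value ϕ* = (α+ψ+τ)(β+τ)(ς+τ)/(ΛςχΦ), where J has a simple
zero eigenvalue. The right null vector w is solved row-by-row with the
free scale fixed at w₂ = 1; the left null vector has support only on
the E and I₁ rows with v₃ = (ς+τ)/(Φς)·v₂, scaled so v·w = 1. Both are
cross-checked against SVD null spaces (cosine similarity > 1−1e-8).
Only the incidence term is nonlinear, so the normal-form sums collapse
to a = 2v₂w₁w₃ϕ*χ and b = v₂w₃S⁰χ. Note a is homogeneous of degree one
under the rescaling (w, v) → (cw, v/c) that preserves v·w = 1; its
*sign* — the quantity that decides the bifurcation direction — is scale
invariant, and a < 0 < b (forward bifurcation) holds across randomized
draws from the plausible parameter box.

Global-stability claims are checked empirically rather than by
Lyapunov-function verification (a non-goal): from 20 random admissible
initial states, trajectories converge to the DFE below threshold and to
the EEP above it to within 1e-4 at the horizon.

## Simulation

The integrator is classical fixed-step RK-4, matching the reference
experiments and keeping runs bit-reproducible; there is deliberately no
adaptive fallback. Reference runs use h = 0.001 with t_end = 500 (long
enough that both reference scenarios reach max|dy/dt| < 1e-8; no final
time is stated in the source experiments). Stored trajectories are
thinned to every 100th step by default; steady-state detection
re-evaluates the exact vector field on the trailing window, so it does
not depend on the storage stride. Trajectories serialise as CSV
(`t,S,E,I1,I2,R,Q`) at 17 significant digits. Property tests that only
need qualitative convergence (global-stability surrogate, parameter
sweeps) use h = 0.01 and shorter horizons; RK-4's global error at these
settings (≈ h⁴) is orders of magnitude below the tolerances those tests
assert, and the choice keeps the default suite under a minute.

States are not clamped during integration: positivity is a property of
the model, and violations beyond −1e-9 at stored points raise a
`PositivityWarning` and are recorded on the trajectory rather than
silently repaired. Non-finite states abort with the offending time.

## Sensitivity analysis

Local: the normalized forward sensitivity index (elasticity)
Λ_p = (∂R₀/∂p)(p/R₀). Because R₀ is multiplicatively separable in Λ, ϕ,
χ and Φ, their indices are exactly 1; ς has index τ/(τ+ς) (= 1/6 at the
baseline τ = 0.05, ς = 0.25), β has −β/(β+τ), α and ψ have
−α/(τ+α+ψ) and −ψ/(τ+α+ψ), and τ has a three-term rational form. The
closed forms are the contract and are verified against central-difference
elasticities at 1e-6 over random draws; isolated tabulated spot values
in the source that are mutually inconsistent with these formulas (they
cannot all hold at any single parameter point) are not asserted.

Global: Latin hypercube sampling (via `scipy.stats.qmc`, whose
one-draw-per-stratum property is itself asserted) over the nine R₀
parameters, default ±25 % around the baseline — the source states only
"a uniform distribution from its baseline value" — truncated to keep
fractions in [0, 1]. PRCC is computed by the residual-regression route:
rank-transform all columns and the output, regress the target column's
ranks and the output's ranks on all other ranked columns, and correlate
the residuals; p-values use the t statistic with n − 2 − (p − 1)
degrees of freedom. This route is algebraically identical to inverting
the rank correlation matrix but better conditioned near collinearity;
an independent partial-correlation implementation (pingouin) confirms
it to 1e-10 in the tests. Compartment outputs are read from an RK-4
trajectory at t = 50 by default (no evaluation time is stated in the
source); the R₀ output uses the closed form directly, so the reference
design size n = 5000 runs in well under a second.

A resolution caveat established while validating the sign pattern: at
n = 5000 with ±25 % ranges, ψ's true elasticity (−0.0046) is below the
design's noise floor — its PRCC is statistically indistinguishable from
zero and its sample sign is seed noise. The tests therefore assert that
every *significant* PRCC (p < 0.01) matches the elasticity sign, that
the eight well-identified parameters have the correct definite signs,
and that ψ's coefficient is small and non-significant.

## Scenarios, configuration, CLI

Scenarios are flat YAML/JSON documents (versioned schema, unknown keys
rejected, explicit `extends` for inheriting packaged parameter sets).
The `smad` CLI is a thin wrapper: `r0`, `equilibria`, `stability`,
`simulate`, `sweep`, `nfsi`, `prcc`, `report`, each emitting JSON or
CSV; commands that write files also write a one-line JSON manifest
(command, scenario, seed, version) beside the output, and all failures
exit nonzero with a structured message on stderr. Nothing in the
analysis pipeline is stochastic except LHS, which takes an explicit
seed; `run_report` records the seed it was handed for provenance.

## Known limitations

- Deterministic mean-field dynamics only: no demographic stochasticity,
  no network or age structure, no seasonality (all out of scope).
- The model is not fitted to data; parameter values are literature-pinned
  constants, and conclusions are qualitative (thresholds, directions of
  influence) rather than forecasts.
- Fixed-step RK-4 will mis-handle stiff parameter regimes far outside
  the plausible box; the integrator guards (positivity and finiteness
  checks) detect rather than prevent this.
- PRCC assumes monotone input–output relationships; for R₀ this holds
  exactly (the elasticities have fixed sign), but compartment outputs
  at finite times need not be monotone in every parameter.
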