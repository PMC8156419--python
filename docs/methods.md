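# Methods

## Structural model

The model tracks an oral serine bolus through a gut depot into a single
central (plasma) compartment that also receives a constant endogenous input:

* gut depot: `dD/dt = -k_abs · D`, with each bolus added instantaneously to
  `D` at its dose time (right-continuous);
* central: `dC/dt = (F/V_D)·k_abs·D + k_gen/V_D - (CL/V_D)·C`.

Only the ratios F/V_D, CL/V_D and k_gen/V_D are identifiable from oral
concentration data: multiplying V_D, F, k_gen and CL by a common factor
leaves every prediction unchanged. The package therefore estimates the
four-ratio form everywhere, and keeps the five-parameter form only for the
naive pooled fit, which exists to demonstrate that flat ridge (its objective
Hessian is verified to be ≥ 100× worse conditioned than the ratio form's).

**Initial condition.** Pre-dose sampling follows an overnight fast, so the
system starts at the production/clearance steady state B = k_gen/CL. With
that start the baseline contribution stays constant for all time and each
dose adds an independent Bateman term

    ΔC(τ) = (F/V_D)·k_abs·A·(e^(-k_e·τ) - e^(-k_abs·τ))/(k_abs - k_e),  k_e = CL/V_D,

active only for τ = t - t_dose ≥ 0. The coincident-rate limit
(k_abs → k_e) is evaluated through the stable difference quotient
τ·e^(-k_e·τ)·φ((k_abs-k_e)τ) with φ(x) = (1-e^(-x))/x, so no branch on
parameter values is needed and the solution stays accurate when the rates
are within 1e-8 of each other.

**Units.** All internal state is µmol, µmol/L and hours. Gram doses are
converted at the I/O boundary with the molar mass of L-serine,
105.09 g/mol.

**Two-compartment extension.** First-order exchange between the central
concentration and a peripheral pool (k23 out of, k32 back into the central
compartment, both on the central amount scale). The system stays linear, so
instead of numeric integration the solution is the standard
three-exponential per dose, with hybrid rates

    λ1,2 = ½[(k_e + k23 + k32) ± sqrt((k_e + k23 + k32)² - 4·k_e·k32)],

chosen for speed: the compartment-comparison study fits the two-compartment
model hundreds of times. When any two of (k_abs, λ1, λ2) agree to better
than 1e-7 relative, the solver falls back to the LSODA ODE path. The edge
case k23 > 0, k32 = 0 (a leak with no return) is handled exactly as extra
clearance on the central side. An independent ODE integrator
(`simulate_concentration_ode`, LSODA at rtol 1e-10) is part of the public
surface and serves as the oracle in the tests: the closed forms agree with
it to better than 1e-6 relative across random parameter sets.

**Flip-flop convention.** The oral one-compartment curve is exactly
invariant under swapping k_abs ↔ CL/V_D while rescaling F/V_D and k_gen/V_D
by their ratio, so individual and pooled fits have two equivalent global
optima. Estimates are canonicalized to the branch with k_abs ≥ CL/V_D
(absorption faster than elimination), which matches the observed serine
kinetics; without such a convention "parameter recovery" is ill-posed.

## Residual error and individual fits

Residual error is Gaussian with standard deviation

* constant: σ_a;
* proportional: σ_p·f;
* combined: sqrt(σ_a² + (σ_p·f)²) — variance-additive, the standard
  pharmacometric convention.

Individual fits maximize the exact Gaussian likelihood (2π constants
included, so objectives are directly comparable across engines) over the log
structural parameters. The overall error scale is profiled out in closed
form (extended least squares): for the combined model only the shape ratio
σ_p/σ_a is optimized and σ_a follows as
`σ̂_a² = mean((y-f)²/(1+(r·f)²))`. Profiling removes a badly scaled joint
descent direction between sigmas and structural parameters; on noiseless
data the concentrated objective descends essentially to machine precision,
which is what makes exact-recovery tests meaningful. Optimization is
multistart L-BFGS-B (default 8 starts, log-uniform ±1 perturbations from a
seeded generator) because the likelihood has genuine local minima; wild
line-search points are clipped into a finite box with a quadratic penalty
rather than returning infinities that would abort the line search.

The QQ/normality report standardizes weighted residuals, pairs them with
Blom plotting positions, and summarizes tail straightness as the mean
absolute gap between ordered standardized residuals and normal quantiles
over the outer 20% — smaller is straighter. A residual vector with
essentially zero variance short-circuits to a degenerate flag.

## Population model

Individual parameters are lognormal, `param_i = exp(θ + η_i)` with
`η_i ~ N(0, Ω)`, Ω diagonal (the analysis reports per-parameter
variabilities and no covariances). The marginal likelihood integrates η out
per subject; the package uses the Laplace approximation at the per-subject
posterior mode:

    -2·log L_i ≈ 2·g(η̂_i) + log det H_i - k·log 2π,

with g the joint negative log posterior and H its η-Hessian at the mode.
Mode finding is a damped Newton iteration vectorized across all subjects
(finite-difference gradient/Hessian, per-subject backtracking, positive
definite regularization toward the prior precision), converged to a 1e-8
gradient norm so the outer objective is smooth enough for finite-difference
gradients. An adaptive Gauss–Hermite integrator (mode- and
curvature-adapted, tensor grid, ≤ 2 free etas) is kept as an independent
oracle; Laplace agrees with 64-node quadrature to better than 1e-3 relative
on reduced models. An indefinite η-Hessian at a trial point gets an
eigenvalue-floored log-determinant (keeping the outer objective finite) and
the subject flagged not-ok; with all variances zero the objective is exactly
the fixed-effects -2·log-likelihood.

The outer problem optimizes θ, the random-effect SDs and the error
parameters with L-BFGS-B (outer finite-difference step 1e-6, well above the
residual noise of the inner solve). SDs are optimized on the **linear**
scale with a hard lower bound at zero: on a log scale the likelihood is
asymptotically flat as ω → 0 and the optimizer stalls; on the linear scale
an unsupported variance can land exactly on the boundary.

**Variance collapse.** After the fit, any free ω² below 1e-4 (CV < 1%) is
flagged "small" and the model refitted with it pinned at zero. In addition,
small variances (ω² < 0.0225, CV < 15%) are tested against zero by the
boundary-corrected likelihood-ratio test: the null value lies on the
parameter boundary, so the 5% critical value is χ²₁(0.90) = 2.706 rather
than 3.84. Variances whose removal costs less than that are eliminated
backward, smallest first. This reflects how fitted variances "too small to
produce noticeable variability" are fixed in practice; the Laplace
likelihood routinely has shallow optima at tiny nonzero ω² for parameters
with no true variability, and a hard threshold alone misses them.

**Standard errors** of θ come from the finite-difference Hessian of the
marginal -2·log-likelihood over the θ block, conditional on the variance
components at their estimates, and are reported as exp(θ̂ ± SE) ranges.

**Model comparison.** Nested fits are compared by Δ(-2LL) against
χ²(df = extra parameters); the decision record also carries the relative
changes in shared fixed effects and the maximum relative change between the
typical-subject curves for a standard 20 g dose, so a statistically
significant but practically irrelevant extension (the usual fate of a second
compartment here) can be rejected on parsimony.

**Covariate screen.** Per-subject empirical-Bayes η modes are correlated
(Pearson and Spearman) with weight and height; p-values come from seeded
permutations of the covariate labels (default 10,000). The verdict is "no
covariate" when every p-value clears 0.05. Constant covariates are skipped
with a note. Affine re-encoding of a covariate provably leaves both
statistics unchanged.

## Synthetic trials

The generator emulates the calibration-trial design: 10 subjects, 20 g
(≈ 190,313 µmol) at t = 0, a second 20 g bolus at a per-subject uniform time
in [25.3, 26.3] h, eight dense samples on the dosing day and one pre-dose
sample at the second dose time. The dense-day grid
(0, 0.5, 1, 2, 3, 4, 6, 8 h) is a declared convention — only the sample
count is fixed by the design — and is configurable, as is the decision to
place the next-day sample immediately before the second dose. Default
generating values are the population estimates (k_abs 2.88/h,
F/V 0.00429/L, CL/V 0.288/h, k_gen/V 29.6 µmol/L/h) with ω² = 0.4² on
absorption and 0.1² on elimination, none on the other two — the observed
pattern of large absorption spread, modest elimination spread, and
negligible variability elsewhere — and 10% proportional error. Weight is
lognormal (mean 82.8, SD 16.5 kg, truncated to the observed 61.0–114.8
range) and height normal (177.0 ± 8.3 cm, truncated to 166.0–192.5);
truncation is by resampling. Concentrations below the LLOQ floor (default
1 µmol/L) are clamped by default (alternatives: censor to LLOQ/2, or drop).
All randomness flows from one mandatory integer seed through
`numpy.random.default_rng` (PCG64), so a seed reproduces a trial exactly.

What the generator does **not** emulate: the co-administered cocktail agents
and any interaction with them, food effects and diurnal variation of
production (production is constant by assumption), assay-specific error
structure beyond the chosen residual model, and dropout or sampling-time
jitter. Passing recovery tests therefore demonstrate estimator correctness
under the stated statistical assumptions, not robustness to these real-data
features.

The recovery harness (`recovery_experiment`) runs simulate-fit replicates
(replicate r reseeded at seed + r), starting each fit from neutral
round-number values (k_abs 2/h, F/V 0.005/L, CL/V 0.3/h, k_gen/V 30, all
four variances free at ω² = 0.04) rather than from the generating values,
and reports signed median relative bias, relative RMSE, ± SE coverage (when
requested) and the per-parameter collapse frequency. Failures are counted,
never raised.

## Problem sizes and numerical defaults

The shipped studies use the trial's own scale: 10 subjects × 9 observations,
20 replicates for recovery and for the compartment-LRT null study — large
enough for stable medians and ≥ 80% frequency checks, small enough to run
on a laptop in minutes. Other defaults worth knowing: inner Newton max 50
iterations; multistart perturbations ±1 natural-log unit; individual-fit
convergence at ftol 1e-14/gtol 1e-10 (needed for the exact-recovery
contracts); permutation count 10,000 for the covariate screen (reduced in
some tests for speed); safety bound in the dose planner 30 g/day,
report-only.

## Known limitations

* Laplace is a second-order approximation; with 9 observations per subject
  it tracks quadrature to ~1e-3 relative here, but small-sample bias of
  variance components (visible as mild shrinkage of ω²_k_abs at n = 10) is
  inherited from the method.
* Diagonal Ω only; no covariate model beyond the screen; no SAEM/FOCE
  alternatives.
* The dose-planning chain treats hepatic extraction fractions from animal
  data as fixed inputs and reports, rather than enforces, the safety bound.
* Clearance is linear by construction; saturable elimination and diurnal
  production are out of scope.
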