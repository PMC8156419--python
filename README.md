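# serinepk

Population pharmacokinetics of oral L-serine in humans.

Serine is unusual among orally dosed compounds: the body synthesizes it
continuously (mostly in the kidney), so plasma concentration never returns to
zero but to an endogenous baseline of roughly 100–120 µmol/L. Any PK analysis
of an oral serine dose must carry that production term, and without
intravenous data the absolute volume of distribution V_D and bioavailability
F are not separately identifiable — only ratios are. This package implements
the full analysis workflow for a small oral-dose calibration trial
(n = 10 subjects, 20 g serine on two consecutive mornings, a dense sampling
day plus one next-day sample): structural model, individual and population
fits, model selection, covariate screening, and the physiological arithmetic
that turns fitted ratios into a dose recommendation. It is aimed at
pharmacometricians and quantitative biologists who need a transparent,
fully scripted serine dosing analysis — including a synthetic-trial
generator so every stage is testable without access to clinical data.

## Model

Gut depot with first-order absorption and bolus dosing,

    dD/dt = -k_abs · D + DoseAmt · δ(t - t_dose)

and a central compartment with constant endogenous production and first-order
clearance, written in the identifiable ratio form

    dC/dt = (F/V_D) · k_abs · D + k_gen/V_D - (CL/V_D) · C .

The four adjustable parameters are k_abs (1/h), F/V_D (1/L), CL/V_D (1/h, the
elimination rate constant) and k_gen/V_D (µmol·L⁻¹·h⁻¹). The pre-dose steady
state is B = k_gen/CL, the half-life ln 2/(CL/V_D), and the solution is a
closed-form Bateman superposition over dose events (an optional
central–peripheral exchange k23/k32 extends it to two compartments). The
population model places lognormal inter-individual variability on the
parameters, `param_i = exp(θ + η_i)`, `η_i ~ N(0, ω²)` with diagonal Ω, under
a constant, proportional, or combined residual error model; the marginal
likelihood is maximized with a Laplace approximation at per-subject η modes,
validated against adaptive Gauss–Hermite quadrature. Nested structures are
compared by likelihood ratio against χ² thresholds, and statistically
unsupported random-effect variances are fixed at zero ("collapsed") via the
boundary-corrected χ²₁ test.

## Worked example

```python
from serinepk import (
    DoseEvent, StructuralParams, grams_to_umol,
    simulate_concentration, steady_state_baseline, half_life,
)
from serinepk.synthetic import TrialDesign, default_generating_model, generate_trial
from serinepk.population import fit_population
from serinepk.synthetic import default_fit_init

p = StructuralParams(k_abs=2.88, f_over_v=0.00429, cl_over_v=0.288, kgen_over_v=29.6)
print(round(steady_state_baseline(p), 1), "umol/L baseline")
print(round(half_life(p.cl_over_v), 2), "h half-life")
dose = grams_to_umol(20.0)
c = simulate_concentration(p, [DoseEvent(0.0, dose)], [0.0, 1.0, 2.0, 6.0, 12.0])
print([round(x) for x in c], "umol/L")

subjects = generate_trial(TrialDesign(), default_generating_model(seed=1))
fit = fit_population(subjects, default_fit_init("proportional"), seed=1)
print({k: round(v, 4) for k, v in fit.estimates.items()})
print("collapsed variances:", fit.collapsed)
```

prints

```
102.8 umol/L baseline
2.41 h half-life
[103, 732, 610, 264, 131] umol/L
{'k_abs': 3.3359, 'f_over_v': 0.0042, 'cl_over_v': 0.2834, 'kgen_over_v': 29.7507}
collapsed variances: ['f_over_v', 'kgen_over_v']
```

The simulated 20 g dose rises from the 102.8 µmol/L baseline to a peak above
700 µmol/L within the first hour and is essentially cleared within twelve. The
population refit of the synthetic trial recovers the elimination ratio within
a few percent and correctly pins the variances of the two parameters that
were simulated without inter-individual variability.

The same workflow is scriptable from the shell:

```bash
serinepk report --seed 1 --out-dir results/   # simulate + fits + LRT + covariates + dose report
serinepk physio --out-dir results/            # just the dose-rationale arithmetic
```

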