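# cogsurv

Two-stage vs. joint Bayesian longitudinal–survival modeling of
cognition–mortality associations.

## The problem

In cohorts of older adults, cognitive decline predicts death — and death, in
turn, removes the fastest decliners from the study before their next
assessment. Missingness in the cognitive outcome is therefore *missing not
at random*: a standalone growth model understates decline, and the common
two-stage procedure (estimate each person's level and slope, then use the
point estimates as survival predictors) both ignores stage-1 uncertainty and
inherits the selection bias. `cogsurv` implements the full comparison
between that two-stage procedure and the shared-random-effects joint model,
for researchers in cognitive epidemiology and biostatistics who want to
study (or teach) the difference on reproducible synthetic cohorts.

## Models

Longitudinal sub-model for a cognitive factor score at centered age
`a = age − 65` (quadratic change fixed-only; random intercept and linear
change):

    Y_ti = B0 + B1·a + B2·a² [+ covariates] + u0_i + u1_i·a + e_ti,
    (u0, u1) ~ N(0, Σ_u),  e ~ N(0, σ²)

Proportional-hazards sub-model on time since study entry, with a
piecewise-constant baseline:

    h_i(t) = h0(t) · exp(γ'w_i + α1·u0_i + α2·u1_i)

`α1` and `α2` are the shared parameters: the joint model estimates both
sub-models simultaneously, while the two-stage pipeline replaces
`(u0_i, u1_i)` in the hazard by their posterior means from a standalone
longitudinal fit. All fitting is MCMC (conjugate Gibbs for the growth
model, Metropolis-within-Gibbs for the joint model); see `docs/methods.md`.

The package ships a synthetic cohort generator emulating a large
repeated-measures aging study (≈6,000 adults aged 50–87, up to four
assessments at ~4-year gaps, ~75% deceased at a 29-year mortality census),
in which scores follow the growth model above and death times are drawn
from the shared-effect hazard — so the MNAR mechanism, and the true
parameters, are known exactly.

## Worked example

```python
from cogsurv import (MCMCSettings, ModelSpec, extract_shared_association,
                     fit_joint, run_two_stage, scaled_hazard_ratio,
                     simulate_cohort)
from cogsurv.synthetic import recovery_config
import numpy as np

# cohort at known truth: alpha2 = -1.0, var_u1 = 0.09, ~60% deaths
cohort, panel, latents = simulate_cohort(recovery_config(seed=7, n=800))
spec = ModelSpec(form="quadratic")
mcmc = MCMCSettings(chains=2, iterations=2000, burn_in=500, seed=1)

joint = fit_joint(panel, cohort, spec, mcmc)
two_stage = run_two_stage(panel, cohort, spec, mcmc)

print(extract_shared_association(joint))
print("two-stage alpha2: %.3f [%.3f, %.3f]"
      % (two_stage.ph.mean("alpha2"), *two_stage.ph.ci("alpha2")))
print("HR per 1 SD of slope:",
      round(scaled_hazard_ratio(joint.summary.mean("alpha2"),
                                np.sqrt(joint.summary.mean("var_u1"))), 3))
```

Output:

```
            mean    ci_low   ci_high  significant
param
alpha1 -0.003869 -0.015539  0.007622        False
alpha2 -0.960014 -1.470738 -0.451762         True
two-stage alpha2: -0.854 [-1.295, -0.424]
HR per 1 SD of slope: 0.753
```

The joint estimate of the decline–mortality association (−0.96) sits on the
generating value of −1.0, while the two-stage estimate (−0.85) is
attenuated toward zero — the package's central phenomenon. The scaled
hazard ratio says a person declining 1 SD *less* than average has about
0.75 times the mortality hazard.

The 16-cell analysis grid (framework × sex × domain × covariates) runs via
`run_grid` or from the shell:

```bash
cogsurv simulate --seed 1 --out sim/
cogsurv run-grid --panel sim/panel.csv --cohort sim/cohort.csv --out fits/
```

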