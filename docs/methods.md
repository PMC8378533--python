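# Methods

## The problem

In longitudinal studies of cognitive aging, participants who decline fastest
are the most likely to die before their next assessment. Missingness in the
cognitive outcome is then *missing not at random* (MNAR): it depends on the
very quantity being modeled. A standalone growth model fitted to such data
understates decline, and the common two-stage approach to
cognition–mortality associations — estimate each person's level and slope
first, then use those point scores as survival predictors — both ignores the
uncertainty in the scores and inherits the selection bias. The
shared-random-effects joint model addresses this by estimating the growth
model and the mortality model simultaneously, linked through the
person-level effects.

## Models

**Growth sub-model.** For factor score `Y_ti` of person `i` at centered age
`a = age − 65`:

    Y_ti = B0 + B1·a + B2·a² [+ B3·sa_i + B4·sa_i·a + B5·smoker_i + B6·srh_i]
           + u0_i + u1_i·a + e_ti

with `sa` the centered entry age, SRH centered at 3, `(u0, u1) ~ N(0, Σ_u)`
and `e ~ N(0, σ²)`. Quadratic change is a fixed effect only: with at most
four occasions per person, person-level quadratic deviations are not
identified. Intercept-only and linear forms are nested in this model for
screening via deviance/BIC; the pseudo-R² reported for a fit is the
proportional reduction of σ² relative to the intercept-only
(unconditional-means) fit on the same data.

**Hazard sub-model.** Time runs from study entry (entry age is a covariate,
not the time scale — the source analysis reports an entry-age coefficient,
which implies the same convention). The hazard is

    h_i(t) = h0(t) · exp(γ' w_i + α1·u0_i + α2·u1_i)

with a piecewise-constant baseline `h0` (cut points at the deciles of the
observed event times). Because the association runs through the
time-constant random effects, each cumulative hazard is
`H0(t)·exp(η_i)` in closed form; no quadrature is needed anywhere in the
likelihood. Administrative censoring occurs at the census horizon. Tied
event times (measure-zero for simulated continuous times) are broken by a
seeded jitter at the 1e-8 scale.

**Two-stage procedure.** Stage 1 fits the growth model alone and extracts
posterior-mean `(u0_i, u1_i)` scores; stage 2 feeds them into the hazard
model as fixed predictors. Stage-1 uncertainty is deliberately not
propagated — that is the procedure being evaluated, and the output metadata
records the provenance of the scores so the no-leakage property is testable.

**Joint model.** The two sub-models share `(u0_i, u1_i)`; with
`α1 = α2 = 0` the joint log-posterior decomposes exactly into the two
standalone log-posteriors (a property the tests assert to 1e-10).

## Estimation

All models are fitted by MCMC written directly in numpy/scipy:

- Growth model: Gibbs sampling. Fixed effects and the residual variance are
  conjugate (normal, inverse-gamma); the 2×2 random-effect covariance is
  conjugate inverse-Wishart; each person's `(u0, u1)` has a closed-form
  bivariate-normal conditional, solved explicitly so the update vectorizes
  over persons.
- Hazard model: the baseline levels are conjugate gamma given the
  coefficients (piecewise-exponential likelihood); the coefficients move by
  component-wise adaptive random-walk Metropolis (Robbins–Monro tuning to
  ~44% acceptance during warm-up, frozen afterwards).
- Joint model: Metropolis-within-Gibbs combining the two. Person effects
  are proposed from their *longitudinal* full conditional and accepted
  against the survival factor alone — an independence proposal whose
  acceptance ratio involves only that person's hazard terms, so the update
  stays fully vectorized.

Two mixing devices matter in practice. First, a translation group move
shifts `(B0, B1)` against the random-effect means (the observation mean is
invariant under it); it is conjugate in the standalone model and
Metropolis-corrected against the survival factor in the joint model.
Without it the fixed-effect effective sample size was two orders of
magnitude lower. Second, proposal scales adapt only during warm-up, so the
retained chains are valid MCMC.

**Priors.** Broad normals on fixed effects (SD 100) and hazard coefficients
(SD 10), inverse-gamma(0.01, 0.01) on the residual variance,
gamma(0.01, 0.01) on baseline hazard levels, and inverse-Wishart(df 4,
scale diag(1, 0.01)) on Σ_u. The inverse-Wishart (rather than half-t/LKJ
factorizations) keeps the covariance update conjugate in a hand-rolled
sampler; at the cohort sizes used here (hundreds to thousands of persons)
the data dominate all of these priors. All are overridable via the priors
dataclasses.

**Protocol.** Desk-scale default: 2 chains × (500 warm-up + 2,000 kept)
draws. `MCMCSettings.full_scale()` restores the full protocol of 20,000
iterations with 3,000 burn-in (read as 3,000 warm-up + 17,000 kept).
Convergence is declared at split-chain rank-normalized R-hat < 1.05 and
bulk ESS > 200 (computed via arviz); diagnostics flag failures rather than
silently passing, and trace/autocorrelation/density plots can be exported
per parameter. Deviance is not uniquely defined under MCMC; it is computed
as −2 × the *marginal* (random-effects-integrated) log-likelihood at the
posterior means, and BIC adds `k·ln(N_obs)` with `k` counting all free
parameters including variance components.

## Synthetic cohorts

The generator emulates the design of a large British longitudinal study of
cognitive aging whose raw data are not deposited: N = 5,954 with 70.5%
women; entry ages from a truncated normal calibrated to median 65 and IQR
60–70 on [50, 87]; 24.7% smokers; SRH drawn from (0.05, 0.10, 0.25, 0.30,
0.30) over 1..5, giving median 4 and IQR 3–5; up to 4 assessments, the
first at entry and subsequent gaps ~ Uniform(3, 5) years; mortality
followed for 29 years after entry. Scores follow the growth model with
truth set to the published joint-model estimates per sex × domain;
crystallized (Gc) and fluid (Gf) cohorts are generated independently
(cross-domain dependence is not reported in the source and is not
modeled). Death times are drawn by inverting `S(t) = u` under the
shared-effect hazard — exact for the piecewise-constant baseline — and the
panel is truncated at death or census, which *is* the MNAR mechanism.

Two generator features are calibrated rather than taken from a printed
value, both frozen after a one-off numerical calibration:

- the Gompertz-like baseline (rate ratio 1.55 per 5-year band, matching a
  mortality doubling time of 7–8 years) is scaled per sex so ~71% of women
  and ~84% of men die before census (74.8% overall);
- a monotone, non-informative per-occasion continuation probability
  (0.682, 0.625, 0.552) reproduces the observed mean of ~2.2 completed
  assessments. Real attrition is partly informative beyond death; the
  source treats non-death dropout as unmodeled, and so does the generator —
  passing tests therefore say nothing about non-death informative dropout.

Presets: `default_config()` (the full design), `recovery_config()`
(single-stratum Gf-like truth, α2 = −1, ~60% deaths, for recovery
harnesses), and `covariate_linked_config()` (smoking/SRH affect both
scores and hazard, for selection-effect analyses). An optional
`srh_dependence` knob links SRH to the latent intercept; it is off by
default because the source is silent on that mechanism.

What the generator does *not* emulate: the factor-analysis step producing
the scores (scores are emitted directly), raw task batteries, non-death
dropout, cause-of-death structure, and any Gc–Gf correlation.

## Reporting conventions

- **Scaled hazard ratios** are `exp(coef × SD)` per predictor. For joint
  fits the SD of a shared effect is the posterior-mean random-effect SD;
  for two-stage fits it is the empirical SD of the stage-1 posterior-mean
  scores (shrunken). The model-SD convention reproduces the published
  joint-model cells within table rounding; the two conventions differ for
  two-stage fits and both are available.
- **ΔZ per decade**: the model-implied fixed-effect change over a
  configurable 10-year window (default ages 70→80) at reference
  covariates, divided by a configurable standardizing SD (default: the
  baseline between-person SD `sqrt(var_u0 + var_resid)`, draw by draw).
  This is a convention — the source's exact definition is not recoverable —
  so the window and SD choice are recorded in the output and alternative
  windows can be reported side by side.
- **Occasion summaries** count cumulative deaths at occasion k as deaths
  before the stratum's median time-on-study of that occasion (a documented
  convention; the source table does not define its rule).

## Problem sizes used in the checks

The test-suite harnesses run at sizes chosen for a single desktop CPU: the
parameter-recovery and attenuation studies use 20 replicate cohorts of
n = 1,000 at 2 chains × 2,000 kept draws; the selection-effect analysis
uses one cohort of n = 3,000; simulator calibration is checked at the full
n = 5,954. The acceptance script's published-table targets are pure
arithmetic on printed inputs and run in well under a second.

## Known limitations

- The joint sampler's latent update relies on the survival factor being a
  modest correction to the longitudinal conditional; under extremely strong
  associations (|α2·SD(u1)| ≫ 1) acceptance rates would drop and a tailored
  proposal would be needed.
- Fitting is sex-stratified only; there is no pooled model with
  sex-by-parameter interactions.
- The two-stage/joint contrast in CI width observed in the source depends
  on how strongly MNAR selection depresses the standalone slope-variance
  estimate; at the simulation strength used here the attenuation of the
  point estimate reproduces robustly, while the width contrast is weaker
  than in the source data (see the acceptance harness output).
- Competing risks, frailty beyond the shared effects, current-value or
  cumulative-effect association structures, and dynamic prediction are out
  of scope.
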