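# Methods

This note documents the statistical machinery implemented in `spillpower`:
the structural model, the estimators, the calibration search, the power
analysis, the synthetic experiment generator, and the numerical and design
choices behind each.

## Structural model

Two latent Gaussian "activation systems" mediate between interventions and
behaviors.  With treatment dummy `T` and nudge dummy `IV`, both
Bernoulli(1/2) and independent:

```
U1 | T          ~  Normal(phi1 * T, sigma_u1)
U2 | U1, PEB1   ~  Normal(phi21 * U1 + phi22 * PEB1, sigma_u2)
```

`U2` depends on the *realized* draw of PEB1, not on its success
probability: the behavioral feedback runs through what the respondent
actually did.  Two observation models share this latent chain:

- **binary**: `PEB1 ~ Bernoulli(expit(a1 + beta_u1*U1 + beta_iv*IV))` and
  `PEB2 ~ Bernoulli(expit(a2 + beta_u2*U2))`;
- **continuous**: the same linear predictors as Gaussian means with SDs
  `sigma_peb1`, `sigma_peb2`.

In the continuous model the treatment effects have closed forms
(`closed_form_effects`): ∂T PEB1 = β_U1·φ1, ∂PEB1 PEB2 = β_U2·φ22,
∂T PEB2 = β_U2·φ21·φ1, and the total effect is their usual
direct + indirect sum.  The binary model has no closed form and is always
handled by simulation.

Parameter defaults and units: all path coefficients are on the latent
(logit, in the binary version) scale and dimensionless; noise SDs default
to 1.  The attractiveness intercepts default to −1.5 in the binary version
(base participation ≈ 18.2%) and 0 in the continuous one; the
autocorrelation φ21 is fixed at 0.6 (binary) / 0.7 (continuous).  These are
the study's non-intervened design constants, not searched by calibration.

## Estimation pipeline

The registered analysis consists of three regressions sharing the sample:

1. stage 1 (OLS): `PEB1 ~ 1 + IV + T`
2. stage 2 (2SLS): `PEB2 ~ 1 + PEB1_hat + T`, with δ′ the direct effect
   and β′ the behavior-on-behavior effect;
3. total (OLS): `PEB2 ~ 1 + T`, with τ the total effect.

Conventions:

- **Robust SEs** are HC1 (finite-sample-scaled sandwich), the common
  default for linear probability models.  The 2SLS covariance uses
  residuals evaluated at the *original* endogenous values, as required for
  consistency.  P-values and CIs use the standard-normal reference; the
  smallest design in scope has a few hundred units.
- **First-stage F** is the robust Wald statistic of the excluded
  instrument(s); values above 10 are reported as "strong" by convention.
- **Indirect effect**: the plug-in τ − δ′.  Its variance cannot be read off
  either regression alone because the two coefficients share observations;
  we use the sandwich of the stacked moment conditions of the three
  equations.  The stacked Jacobian is block-diagonal, so the variance
  reduces to `sum_i (psi_tau_i - psi_delta_i)^2` over per-unit influence
  contributions.  No degrees-of-freedom scaling is applied to this stacked
  SE (there is no standard finite-sample correction for stacked GMM);
  per-equation SEs reported to the user remain HC1.
- **Studentized bootstrap CI**: units are resampled with replacement
  (default B = 10,000); each resample contributes the pivot
  `t* = (theta* - theta_hat) / se*` with `se*` the same stacked sandwich
  recomputed on the resample, and the equal-tailed interval is
  `[theta_hat - se * q_{0.975}(t*), theta_hat - se * q_{0.025}(t*)]`.
  Resamples with a constant T, IV or PEB1 (or a singular design) are
  redrawn, up to 100 rounds; if fewer than B/2 resamples are estimable the
  bootstrap aborts with an error.  The indirect effect is declared
  significant iff the interval excludes zero.
- **Moderation**: the Study-2/3 systems instrument {PEB1, PEB1×moderator}
  with {IV, IV×moderator} (just-identified, two first-stage equations);
  the Study-3 contract adds T×moderator to the exogenous block.
- **Robustness estimators**: a Newton-fitted probit for the participation
  models, and the Rivers–Vuong control-function probit (first-stage OLS
  residual added to the probit; its z-test is the exogeneity diagnostic).
  The control-function second step conditions on the estimated residual;
  its reported SEs do not propagate first-step noise, which is the usual
  two-step diagnostic practice and adequate for sign/significance checks.
- **Multiple testing**: Benjamini–Hochberg step-up, applied once per
  results table (one family per table).

### Computational core

All three equations are linear in at most a handful of regressors, so the
bootstrap is vectorized: a batch of resamples is a `(B, m)` array of
multiplicity weights over design points, and every estimate, sandwich and
influence sum is an einsum over that batch.  When both behaviors are binary
and there is no extra exogenous block, a resample is equivalent in
distribution to a multinomial count vector over the 16 distinct
(T, IV, PEB1, PEB2) cell types, which makes B = 10,000 resamples essentially
free; continuous outcomes or covariates fall back to explicit row gathering
in memory-bounded chunks.  Exact equality of the weighted and
row-replicated computations is covered by a test.

## Effect-size scale

Scenarios are specified in Cohen's d (pooled-SD standardized mean
difference, unbiased group variances, no Hedges correction).  The d of the
direct effect is δ′ divided by the pooled SD of PEB2 across treatment
groups — the analysis never states a group contrast for the direct effect,
so standardizing the 2SLS coefficient by the same SD used for the total
effect keeps the printed subtraction rule exact:
`d_indirect = d_total - d_direct` by construction.

## Calibration

`calibrate_scenario` finds structural parameters whose measured d's match a
scenario's five targets within ±0.01, following the registered three-step
outer loop:

1. fix the entry/exit signals: β_U1 is held at its initialization (1.0) —
   the T→PEB1 effect depends on β_U1 and φ1 only through their combination,
   so searching both would be redundant — and β_U2 is root-found on the
   total-spillover d;
2. root-find φ1 on d(T→PEB1) and β_IV on d(IV→PEB1);
3. root-find φ22 on the indirect d (equivalently the direct/indirect split,
   since the total is pinned by step 1);

repeated until all five measured d's converge jointly.  Each adjustment is
a bracketed Brent root-find on the measured-minus-target gap, evaluated on
a common-random-numbers noise panel of 1,000,000 units so the inner
objective is deterministic and (empirically) monotone; brackets are
(0, 5].  Inner convergence is declared at 0.4× the tolerance so that panel
Monte-Carlo error (d standard error ≈ 0.002 at the panel size) cannot push
the final check out of band; the final acceptance check draws a fresh
5,000,000-unit sample and requires all five gaps ≤ 0.01.  Non-convergence
raises an error reporting the residual gaps — some target combinations are
structurally impossible because every parameter moves the pooled variance
of PEB2.

The calibrated solution is not unique; only the measured effect sizes are
guaranteed, never the raw coefficients.

## Power analysis

For each (scenario, n-per-arm) cell the study is simulated `reps` times
(default 1000; the shipped acceptance runs use 400) at total n = 2×N with
stochastic Bernoulli(1/2) assignment — arms are not hard-balanced, matching
the sampling equations.  Decision rules per estimand: robust-p < α for the
LPM of PEB1 on T, the OLS of PEB2 on T, and the 2SLS δ′; CI-excludes-zero
for the indirect effect, with an inner bootstrap of B = 999 (quantile
accuracy is ample for a 5% decision; B = 10,000 is available for fidelity
runs).  Each replicate draws from its own seed substream, so cells are
order-independent and bit-reproducible.  Degenerate replicates are dropped
from the denominator and counted; more than 5% triggers a warning.

Sensitivity sweeps re-run the spillover estimands while (a) recalibrating
only β_IV to target instrument strengths d ∈ {0.2, 0.4, 0.6, 0.8}, or (b)
fixing an attractiveness intercept at the five levels mapping to base
probabilities 0.01–0.40.

## Synthetic experiment generator

`generate_experiment` emulates the three-study respondent table: study-1
arms {placebo, control, win–win, doom} (the doom narrative and control
carry into studies 2–3), nudge assignment, the Study-2 difficulty and
Study-3 petition-domain manipulations, participation/rounds/performance in
the real-effort task, petition signing, and survey covariates.  Outcomes
flow through the binary structural mechanism; the logit intercepts and the
nudge coefficient are solved by Gauss–Hermite integration over the latent
noise so that the configured *marginal* anchors hold exactly in
expectation: 50.3% baseline participation, +38.9 pp nudge uplift (≈70%
overall), 85% of participants completing all 30 rounds, 27.2% signing the
environmental petition and 38% the health petition.  Injected causal
effects (arm shifts on the latent activation, the PEB1→PEB2 path,
moderation shifts) default to zero.

Choices where the real data's fine structure is unknown, exposed as
configuration rather than claims: rounds of non-completers follow a
truncated geometric on 1–29; per-round correctness is Bernoulli with a
difficulty-dependent rate (0.34 hard / 0.50 easy); covariate marginals use
bracket frequencies resembling the published descriptives, independent of
assignment.  What the generator does **not** emulate: attention-check
exclusions, item-level survey responses, any real joint distribution of
covariates, or time-of-day/ordering effects — so passing tests demonstrate
estimator correctness under the structural model, not fidelity to any
particular real dataset.

## Numerical choices

- Inverse logit via `scipy.special.expit` (branch-free, stable);
  probabilities are never clamped — in-scope parameters do not saturate.
- Batched solves guard against singular systems by determinant screening;
  affected resamples are flagged degenerate, never silently patched.
- Root-finds use Brent with `xtol = 5e-4` on parameters, well below the
  d-resolution the ±0.01 tolerance requires.
- All randomness flows from `numpy.random.Generator` seed sequences; a
  single root seed spawns independent substreams per replicate.

## Known limitations

- The equal-tailed percentile-t interval for τ − δ′ undercovers when the
  instrument or the treatment→PEB1 path is weak at small n (measured ≈0.89
  at n = 500 under middle-scenario-strength continuous parameters, against
  ≈0.95 under strong identification): the statistic is then a weakly
  identified ratio/product and its pivot is not stable across samples.
  Consistently, the CI-excludes-zero rule is conservative at the exact
  product null.  This mirrors the behavior of bootstrap mediation inference
  generally and is a property of the procedure, not of its implementation.
- With an irrelevant instrument (β_IV = 0) the decomposition is
  unidentified; δ′ and the indirect effect are then meaningless and the
  bootstrap test's rejection rate is not α.  The power sweeps therefore
  start at instrument strength d = 0.2.
- The probit-based robustness estimators assume no perfect separation;
  separation raises an explicit error rather than returning divergent
  coefficients.
- Power runs at the shipped 400 replicates carry a binomial Monte-Carlo SE
  of about 1.5–2.5 percentage points per cell; the registered 1000-replicate
  setting is a flag away.
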