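# Methods

## Trial structure and conventions

A treatment set spans 11 weeks: two 4-week treatment periods (mexiletine /
placebo, order block-randomized independently per set with probability ½
each), a 1-week washout between them, and 2 analysis weeks.  Patients
complete 1–4 sets, so a trial lasts 11–44 weeks.  Weeks and in-period days
are 1-based integer indices.  Orders are randomized independently across
sets; nothing forbids four identical orders for one patient, which matches
per-set block randomization of size two.

Sign convention, used everywhere: a positive treatment effect *lowers* the
IVR severity score on the active arm.  Outcomes are generated and modeled
as `level − effect·1[active]`.

Every stochastic operation takes a seed; derived sub-seeds come from
`numpy.random.SeedSequence.spawn`, so cohort simulations, MCMC chains and
assurance iterations are independent yet reproducible bit-for-bit.

## Synthetic data generator

The generator emulates the working model of the trial's power study: a
per-patient random intercept `a_i ~ N(0, σ_a²)`, a random treatment-effect
deviation `b_i ~ N(0, σ_b²)`, and i.i.d. within-person residual noise.
Defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| `mu` | 4.21 | IVR points | placebo mean observed in the earlier crossover RCT |
| `beta0` | 1.75 | IVR points | location of the informative treatment-effect prior |
| `beta_subgroup` | 0 | IVR points | no published chloride/sodium difference |
| `sigma_resid` | 1.5 | IVR points | reported within-subject SD (the MCID is half of it) |
| `sigma_intercept` | 1.0 | IVR points | between-patient level spread; no published value, chosen as a plausible fraction of the placebo mean spread |
| `sigma_slope` | 0.5 | IVR points | between-patient effect heterogeneity; no published value, chosen so individual effects plausibly range over ± 1 point |
| observations | 10 per arm per set | — | 14 diary days are scheduled per period; 10 usable calls per arm models anticipated missingness |

Outcomes are continuous by default (the normal working model); rounding
and clamping to the ordinal 1–9 IVR scale is an opt-in stress test
(`clip_to_ivr`).  Optional per-patient residual heterogeneity multiplies
each patient's residual SD by a lognormal factor with median 1.

What the generator does **not** emulate: serial correlation of daily diary
scores, carry-over effects surviving the washout, period/time trends,
missing-at-random dropout patterns, and the discreteness of the real IVR
scale (unless clipping is enabled).  Tests passing on this generator
therefore validate the estimation machinery under the trial's own working
assumptions, not robustness to those departures.

## Hierarchical model and sampler

```
y_ij = mu + a_i − (beta0 + beta_g·x_i + b_i [+ γ_s z_set + γ_o z_order])·T_ij + ε_ij
```

* `x_i` is a fixed subgroup contrast, chloride = −½ / sodium = +½, keeping
  `beta0` the overall population mean effect.
* Interaction terms (treatment×set, treatment×order) use centered
  covariates; they are refused with an explicit error when structurally
  unidentifiable (single set, single order).
* Residual variance: `per_patient` mode (the default) draws patient
  variances from a shared scaled inverse-chi-square distribution with
  ν = 4 degrees of freedom whose scale gets its own conjugate gamma
  update; `common` mode uses one variance with a diffuse inverse-gamma
  prior.  Between-patient variances get weakly informative inverse-gamma
  (1, 0.5) hyperpriors — diffuse on the 1–9 outcome scale while keeping
  the complete-pooling limit proper.
* The "flat" prior on `beta0` (and on all other fixed effects) is a proper
  normal with SD 1000, so every posterior is proper.

Inference is a blocked Gibbs sampler: the fixed-effect vector is drawn
jointly from its multivariate-normal full conditional; random effects and
variances from conjugate conditionals.  Two exact *recentering* moves —
translating mass between `mu` and the `a_i`, and between `beta0` and the
`b_i`, with the translation drawn from its exact conditional — remove the
random-walk degeneracy between population means and random-effect
averages (without them the effective sample size of `beta0` drops by a
factor of ~4).  A histogram prior on `beta0` is handled exactly: its full
conditional is a normal likelihood times a piecewise-constant density,
sampled as a mixture of truncated normals with log-space tail arithmetic.

With variances fixed and a single patient the joint fixed-effect update
makes draws i.i.d.; this is the configuration verified against the
closed-form normal–normal posterior.

Diagnostics: split-R̂ and bulk ESS (via arviz) for every reported
parameter; the acceptance gate is R̂ < 1.05 and ESS ≥ 400 for `beta0`.
Failing runs are flagged (`converged = False`, a `ConvergenceWarning`),
never silently accepted.  Single-chain runs report NaN diagnostics.

Patients observed in only one arm stay in the fit (they inform the
intercept) but are flagged: their individual effect is prior-dominated.

A note on shrinkage: the exact "individual posterior mean lies between the
raw patient contrast and the population mean" property holds in the
conjugate configuration where per-patient intercepts are effectively
unshrunk (the model then collapses onto patient-level contrasts).  With
shrunken intercepts a small part of the level misfit leaks into the
individual effect, so the bound holds only approximately; the tests pin
the conjugate configuration.

## Interim analyses

Interim decisions are per patient, after completed sets 1–3, using the
single-patient model (no borrowing from other patients — the interim is an
in-trial advice step) and a **flat** prior only.  Thresholds are inclusive:
P ≥ 0.80 stops for effectiveness, P ≤ 0.20 for ineffectiveness.  Set 4 is
never followed by an interim decision; its data flow into the combined
analysis only.  Incomplete sets (a missing period) are excluded with a
warning.  The interim MCMC effort is configurable; defaults (2 chains,
300 warmup + 1000 kept draws) put the Monte-Carlo error of the reported
probability near 0.01.

## Assurance (expected posterior probability)

Each iteration draws a true mean effect from the truth prior, simulates a
full cohort (30 patients, 15/15 chloride/sodium, 2 sets, 10 observations
per arm per set), fits the hierarchical model with the analysis prior, and
records P(beta0 ≥ 0.75); the mean over iterations is the expected
posterior probability.  The per-iteration fits default to the
common-residual-variance conjugate path with 2 chains × (300 warmup + 400
kept) draws — at this size the posterior of `beta0` is dominated by ~2400
observations and the short chains pass the convergence gate; iterations
that fail it are re-run on a fresh sub-seed and counted.  The
heterogeneous-variance mode is available behind a flag at higher cost.
The acceptance script runs 1000 iterations (Monte-Carlo SE ≈ 0.01, a few
minutes on one CPU); the test suite uses 400.

A structural observation: when the truth prior equals the analysis prior
and the analysis model matches the generator, iterated expectation makes
the expected posterior probability equal the *prior* probability of a
meaningful effect, Φ((1.75 − 0.75)/0.89) ≈ 0.870, for any design size.
The design and the variance components only control how far individual
iterations spread around that center.  Under the documented defaults the
package obtains ≈ 0.86–0.89 depending on seed; the protocol's published
0.82 cannot be recovered exactly because its simulation variance
components and the expert-opinion truth prior are not published — the
package treats the printed N(1.75, 0.89) as both truth and analysis prior
and documents the residual gap.

## Elicitation

Expert opinions are histogram priors on a common bin grid; aggregation is
a linear opinion pool (weighted average of bin probabilities, equal
weights by default).  Linear pooling preserves normalization exactly and
makes the pooled mean the weighted mean of expert means.  Logarithmic
pooling is deliberately out of scope.  The moment-matched normal bridge
uses bin midpoints; an all-mass-in-one-bin histogram has zero midpoint SD
and is rejected with guidance to use the histogram prior directly (the
sampler accepts histogram priors natively).

## Cost-effectiveness

Costs are resource volumes × unit costs (Euro, price year 2014 by
protocol convention; unknown categories raise an error naming them).  The
ICER is Δcost/Δeffect for active minus placebo and is only a ratio when
the signs agree; otherwise a dominance flag (`dominant` / `dominated`) or
`undefined` (zero effect difference) is returned.  Uncertainty: percentile
bootstrap (not BCa — the simplest nonparametric choice), resampling
patients with replacement within arm, 95% by default.  The ICER interval
is suppressed with an explanatory flag whenever resamples mix signs; cost
and effect intervals are always returned.  Arm contrasts are computed
within patients by default.

## Instruments

* EMG: Streib grading is a total monotone step function of the number of
  insertions (out of 10) eliciting myotonic discharges: 0–2 → 0, 3–5 → 1+,
  6–9 → 2+, 10 → 3+.
* Relaxation time: the time from the last downward crossing of 90% of peak
  force to the first subsequent crossing of 5% of peak, with linear
  interpolation between samples (sub-sample precision at realistic
  sampling rates).  Taking the *last* 90% down-crossing means transient
  re-rises above 90% restart the clock; this is the documented resolution
  of the non-monotone-decay ambiguity.
* Transient paresis: 100 × (peak force − minimum force after the peak
  within the 3-s MVIC window)/peak force; a peak at the window end yields
  0% with a warning.

## Numerical and testing choices

* Tolerances in conjugate-oracle tests are 0.01 on posterior mean and SD
  at ≥ 20 000 draws; Monte-Carlo property tests use 3-standard-error
  bands or bounds sized so that a false failure is a < 1% event under the
  measured sampling distribution (e.g. the sequential false-effective rate
  of ~3.5% over three looks is bounded at 6/60 replicates).
* Problem sizes in tests (reduced cohorts of 6–12 patients, 12–60
  replicates, 300–1500 kept draws) were chosen as the smallest sizes at
  which the checked properties are statistically decisive.
* Known limitations: no ordinal likelihood for the 1–9 scale, no serial
  correlation in the generator or model, interim analyses do not borrow
  across patients, and the assurance's truth prior is an assumption where
  the protocol used unpublished expert opinion.
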