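# Methods

This note documents the generative models, estimators, calibration
choices and known limitations of `cogrisk`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The synthetic cohort

`generate_cohort(EffectSpec)` draws one row per participant:

* **Age** — truncated normal, location 45.74, scale 14.55, truncated to
  [18, 84] and rounded to whole years. Asymmetric truncation shifts the
  realized mean up by roughly 0.75 years relative to the location
  parameter; this is a property of the chosen family, not a bug.
* **Gender** — Bernoulli, P(cis female) = 0.663 (the cisgender share of
  the emulated population; non-cisgender categories are out of scope).
* **Risk factors** — 13 scales behind an exchangeable Gaussian copula
  (default latent correlation 0.10). Continuous/ordinal scales are
  latent-normal transforms `mean + sd·z`, rounded and clipped to their
  admissible ranges; binary items threshold the latent at the normal
  quantile of the target prevalence. Clipping at a bound that carries
  appreciable normal mass (depression, hearing handicap, exercise are
  the worst cases) shifts means toward the interior and shrinks SDs by
  up to ~25%; the tests encode distortion-aware tolerances. The copula
  strength is a free parameter: the inter-factor correlation matrix of
  the emulated study is not publicly printed, so a small exchangeable
  positive correlation was chosen once as a realistic default and made
  configurable.
* **Objective cognition latents** — for each of visual working memory,
  cognitive flexibility and model-based planning, an impairment-oriented
  latent `y = U·w + a₁·age_z + a₂·age²_z + g·female + ε` with unit total
  variance (residual SD solved per sample unless `noise_sd` overrides).
  Residuals are correlated across the three outcomes so the *total*
  correlations approach 0.45 / 0.26 / 0.15 (the published
  between-measure structure).
* **Subjective memory** — Bernoulli from a logistic model on the same
  predictors, intercept solved (Brent) so the expected prevalence equals
  the target (default 0.405) exactly on the realized sample.

### Effect injection

The reference effects are *univariate* age- and gender-adjusted
standardized coefficients — one model per factor — not a joint model.
The generator therefore calibrates its weights so that the downstream
univariate fits are centered on the configured targets:

* **Linear outcomes.** With `C` the sample covariance of the coded
  predictors (z-scored continuous, 0/2 binary) and `t` the target
  vector, the weights solve `C·w = diag(Var u)·t`, making each marginal
  projection coefficient exactly `t_j` in-sample.
* **Subjective (logistic) outcome.** Marginal logistic fits attenuate
  conditional coefficients when correlated predictors are omitted. A
  moment-based fixed point (the 16√3/15π logistic–probit approximation)
  provides a starting inflation; it is then sharpened by an exact
  in-sample refinement: the true per-subject probabilities are known, so
  each marginal model is fitted to them as a fractional response (same
  score expectation as the realized Bernoulli draws) and the weights are
  rescaled until every marginal coefficient matches its target to
  5 × 10⁻⁴.

A consequence of in-sample calibration is that coverage of nominal 95%
Wald intervals for the injected effects runs slightly *above* 0.95
(design-matrix variability is removed); the acceptance test asserts the
pooled rate lies in [0.92, 0.98].

All randomness flows from one `SeedSequence` split into named
per-variable streams, so changing the effect configuration leaves the
marginal draws untouched.

### Orientation conventions

One convention is used everywhere: analysis variables and latent traits
are oriented so that **higher = worse cognition / higher risk**.
Education, SES, social network and exercise are protective scales and
are negated before standardization (in both the generator's injection
and the analysis stage). The cohort table's display columns keep natural
orientations (`visual_working_memory` higher = better;
`cognitive_flexibility` time-like, higher = worse; `model_based_index`
on the planning-index scale, mean 0.27, SD 0.33, higher = better);
`prepare()` re-orients them. `attach_task_traits` emits impairment-
oriented standardized traits, so simulated task accuracy *decreases* in
`wm_trait` and completion times *increase* in `flex_trait`.

The age effect on the subjective item deserves a note: the published OR
of 1.04 per "age" is ambiguous in scale and inconsistent with its own
p-value if read per SD; the default standardized logit effect of 0.09
was chosen to be consistent with the reported test statistic.

## 2. Task simulators

* **Grid-search memory task.** Each pick is memory-driven with
  probability `m = logit⁻¹(1.55 − 0.45·wm_trait − 0.30·(k−2) −
  0.20·binding)`; otherwise a uniform guess over the unselected cells
  (correct with probability `(k−c)/(G−c−e)`), run through the
  lives/stopping rule (`lives = k`). The four constants were calibrated
  once, by a grid search over the exact accuracy recursion, so the
  default cohort averages ≈0.80 accuracy with between-subject SD ≈0.07
  (≈0.08 including trial noise), matching the emulated study population.
  Setting `memory_prob=0` gives pure chance behavior, which the tests
  check against the exact enumeration.
* **Trail-making-style task.** Run times are log-normal:
  `log t = μ + slope·flex_trait + N(0, 0.12)` with `μ_A = log 30`,
  `μ_B = log 60`, slopes 0.25/0.30. Moments were derived analytically:
  with unit trait variance the B-form cohort mean/SD is ≈63/21 s after
  censoring, matching the emulated population. With probability 0.01 a
  run is multiplied by 6 (an inattentive pause), which exercises the
  100 s / 300 s censoring rule.
* **Two-step planning task.** Two second-stage states with good-outcome
  probabilities following reflecting Gaussian random walks (SD 0.025)
  inside [0.25, 0.75]; transitions are common with probability 0.8.
  These structural constants follow the canonical two-step literature
  and are configurable. The agent's stay choice is drawn directly from
  the logistic stay model — the mirror of the analysis model — rather
  than from a full hybrid Q-learner; this makes parameter recovery
  well-posed and keeps the index's role as a per-subject covariate
  honest. A Q-learning agent is an explicit non-goal. In cohort
  simulation the model-based weight is tied to the planning trait,
  `b_mb = 0.27 − 0.33·mb_trait`, and stay bias / model-free weight get
  modest seeded spread (0.7 ± 0.3, 0.4 ± 0.3).

## 3. Scoring and the chance-level enumeration

Per-subject memory accuracy is the unweighted mean of per-trial
accuracies (each of the 24 trials contributes equally across set sizes);
a pooled-counts variant is available (`method="pooled"`). The chance
level is computed exactly: the guessing process is an absorbing Markov
chain over states (correct found, errors made) with
`P(correct) = (k−c)/(G−c−e)`, absorbing at `c = k` or `e = L`; the
expectation of `c/(c+e)` at absorption is evaluated by memoized
recursion (the state space is tiny). The geometry guard `k + L − 1 ≤ G`
ensures the grid cannot be exhausted before absorption. The sampling
oracle used in tests exploits the equivalence between without-
replacement uniform picking and a uniform random permutation.

Censoring cut-off comparisons are inclusive (`t ≥ cutoff` excluded),
matching the "100 or more seconds" rule. If every run of a form is
censored the score is flagged missing rather than imputed — the
reference analysis plan does not state this case.

## 4. The model-based index estimator

The stay table has one row per consecutive trial pair: response = stay
indicator, predictors outcome `o = ±1`, transition `τ = ±1` and `o·τ`.
The ±1 coding keeps the interaction orthogonal to the mains under
balance. Per-subject coefficients are penalized ML (ridge 10⁻⁴,
damped Newton with analytic Hessian; Wald SEs from the penalized
Hessian). The ridge guarantees finite estimates for separable players
(all-stay/all-switch), who are flagged `converged=False`. The optional
`pooled_shrinkage` estimator shrinks each coefficient toward the
precision-weighted cohort mean with a method-of-moments between-subject
variance (floored at zero); it approximates the fully hierarchical
regression used in the reference analysis at desk scale and is labeled
as an approximation, not claimed identical (the exact hierarchical
specification lives in unpublished supplementary material). With a
single participant, shrinkage reduces to the per-subject fit.

Per-subject ML at 200 trials carries a small away-from-zero bias
(≈ +0.03 on the cohort mean) visible in the tests' tolerances.

## 5. Association suites

* Continuous variables are z-scored with ddof = 1; binary predictors are
  coded 0/2. The 0/2 coding gives SD 1 only at prevalence 0.5 (at
  p = 0.405 the SD is 2√(pq) ≈ 0.982); each deviation is surfaced in the
  preparation log rather than silently corrected.
* Age enters the univariate association models as the standardized
  linear term only; the quadratic term (z-scored square of z-scored age,
  re-standardized) appears in the descriptive age/gender models.
* Logistic fits use statsmodels ML with Wald 95% CIs (the CI method of
  the reference analysis is unstated; Wald was chosen and labeled); on
  separation or non-convergence the ridge-Newton fallback is used and
  flagged. `or_value = exp(beta)` holds to machine precision by
  construction.
* Binarization flags the worst `round(q·n)` participants per objective
  measure, ties broken by stable (score, participant-order) sort — the
  flagged count is exact and reproducible; whether the reference
  analysis used > or ≥ at the empirical quantile is unstated, so the
  deterministic tie-break is labeled in the log.
* Bonferroni families are per dependent variable: α = 0.05/13 for the
  primary and depression-adjusted suites, α = 0.05/(number of
  significant pairs) for the age-interaction suite. No FDR option is
  offered in the default report.
* The mixed-type correlation summary reports Pearson for continuous
  pairs and, for pairs with the binary subjective item, both the
  point-biserial and the two-step polyserial estimate
  `r_pb·√(pq)/φ(Φ⁻¹(p))`.

## 6. Problem sizes used in validation

The test suite validates the statistical claims at sizes chosen to make
Monte-Carlo error small relative to the asserted tolerances: CI coverage
pools 200 seeds × 52 models at n = 3327; type-I error pools 80 null
seeds × 52 models at n = 2000 (4160 tests); index recovery uses 150
agents × 200 trials; the sampling oracle for the chance enumeration uses
10⁶ draws per geometry. Prevalence calibration is checked at n = 10⁵.

## 7. What the synthetic data do and do not show

The generator reproduces marginal distributions, prevalences, the
between-measure correlation structure, and univariate effect sizes — the
quantities the analysis pipeline consumes. It does not emulate
item-level questionnaire structure, missing-data mechanisms,
non-cisgender categories, country/language covariates, age–risk-factor
correlations, selection bias, or any causal structure among risk factors
(the copula is exchangeable and symmetric). Passing tests therefore
demonstrate that the *pipeline* is correct and well-calibrated under the
stated generative conditions; they cannot certify conclusions about any
real cohort, and mediation-style patterns (e.g. depression-adjusted
attenuation) appear only when a user injects them explicitly.

## 8. Numerical details and degenerate inputs

* Effect injection is skipped (weights zero) when n is too small for a
  stable 13 × 13 covariance solve (n ≤ 15); traits remain defined for
  cohorts of one (standardization degenerates to zeros).
* `prepare` fails loudly, naming the column, on zero variance or missing
  values; at small n rare binaries (stroke, prevalence 1.4%) can
  legitimately be constant, and the pipeline surfaces this as a user
  error rather than fitting degenerate models.
* Residual-correlation targets are clipped to [−0.95, 0.95] and the
  residual correlation matrix is eigenvalue-floored to stay positive
  definite under extreme user configurations.
* The ridge-Newton logistic optimizer uses step halving on the penalized
  objective and is shared between the index estimator and the separation
  fallback of the association suite.
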