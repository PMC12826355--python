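# Methods

`bgcomp` estimates estimands defined on *derived* outcome variables — outcomes
computed deterministically from measured source variables, such as
logBMI = f(height, weight) or microcephaly status = f(sex, gestational age,
head circumference) — when the source variables are partially missing.  Instead
of imputing and analysing in two separate (possibly incompatible) steps, a
single generative model is fitted to the source variables, with the missing
entries treated as part of the joint posterior, and posterior draws of any
estimand are obtained by Monte Carlo g-computation through the derivation
function f.

## The estimation target

The estimand is θ = g(E*₁{E(Y|W_expl)}, …, E*_D{E(Y|W_expl)}): a deterministic
combination g of conditional outcome expectations over D target populations.
Each population may pin explanatory covariates to fixed values (e.g. group
X = 1), draw the rest from a covariate law (by default the empirical
distribution of the observed covariate rows), and may itself depend on unknown
parameters γ_d drawn per posterior iteration.  For each of the M posterior
parameter records, S source rows are forward-simulated per population, f is
applied row-wise, and the means are combined by g.  Both M and S must be large
enough that the two Monte Carlo error sources are negligible; the engine
reports the worst per-draw inner standard error (sd/√S, combined across
populations) alongside the posterior summary, and the total posterior variance
of θ always sits above that inner term.

Per-draw random substreams are derived from a single master seed
(`numpy.random.SeedSequence.spawn`), so runs are bit-reproducible and the
outer loop could be parallelized without changing results.

## Source models

Five model families are built in; each returns the same posterior-draw
container (parameter draws + per-cell imputations + convergence diagnostics).

* **toy** — group ~ Bernoulli(ζ); (Z1, Z2) | group ~ bivariate Normal with a
  common covariance.  No priors for this illustrative model are prescribed
  anywhere, so the package defaults are deliberately weak: Normal(0, 10) for
  the four group means, Exponential(1) for the two standard deviations,
  Uniform(0,1) for ζ and Uniform(−1,1) for ρ.
* **univariate** — Y | x, a ~ Normal(β₀+β₁x+β₂a+β₃xa+β₄a², σ²), X ~
  Bernoulli(π); complete data only (it is the analysis model for
  complete-case and imputation-completed datasets).  Standard-Normal priors on
  all coefficients, Exponential(1) on σ, Uniform(0,1) on π.  Age enters
  untransformed (no silent standardization; a caller can standardize up
  front if desired), exactly as the priors are stated.
* **bivariate** — (log height, log weight) | x, a ~ bivariate Normal with
  mean rows α·d(x,a) and γ·d(x,a), d = [1, x, a, xa, a²]; X ~ Bernoulli(π);
  Uniform(−1,1) on the correlation ρ, Exponential(1) on the two scales,
  Normal(0,1) on all coefficients.
* **bernoulli** — Y ~ Bernoulli(θ) with a Beta(1.26, 2.32) prior by default.
  The model is conjugate, so the posterior Beta(a+Σy, b+n−Σy) is sampled
  exactly (iid) rather than by MCMC; the draws agree with the closed form by
  construction and carry `exact: True` in their diagnostics.  Note the
  default prior's actual median is 32.2%, i.e. Pr(θ < 31.5%) = 0.489 — the
  "half the mass below 31.5%" description circulating with these prior
  parameters is a rounded anchor.
* **bsnmn** — the newborn source model: sex ~ Bernoulli(½); gestational age
  (ga − 39 weeks) ~ skew-Normal(ξ, σ, ω) truncated to a validity window
  (default 24–45 weeks, the viability-to-induction range); head circumference
  | sex, ga ~ q·Normal(curve, ζ₁) + (1−q)·Normal(curve + κ, ζ₂) with
  curve = β₀ + β₁·sex + β₂·Δ + β₃·Δ², Δ = ga − 39.  The skew-normal location
  is ξ = μ − σδ√(2/π), δ = ω/√(1+ω²), so that μ is the component *mean*
  (window truncation shifts it by well under 0.1 weeks at the default scale).
  κ is the affected-component mean *shift* relative to β₀, constrained
  κ ≤ −1; this one-sided constraint is the sole guard against mixture
  label-switching, and a posterior for q piling onto its boundary raises an
  identifiability warning.  Default priors: informative Normal(·, 0.1) on μ
  and the curve coefficients (centred on a term-newborn reference),
  inv-Gamma(2,2) on the three scales, Normal(0,2) on ω, Normal(−2,2)
  truncated above at −1 on κ, Uniform(0,1) on q.

### Handling missing entries

Gradient-free ensemble MCMC cannot carry discrete latent variables, and large
numbers of continuous latent coordinates would cripple it, so the
observed-data likelihood is used throughout: missing binaries (group, sex) are
summed out analytically; a missing height or weight contributes its Normal
marginal; a missing gestational age with an observed head circumference is
integrated out by trapezoid quadrature on a fixed 61-point grid over the ga
window (the same grid supplies the skew-normal truncation constant, keeping
the likelihood self-consistent; against an adaptive-quadrature reference the
grid version agrees to ~2·10⁻³ in log-likelihood).  After sampling, each
retained draw's missing entries are drawn from their exact full conditionals
given that draw — a Rao-Blackwellized scheme whose (parameters, imputations)
pairs are draws from the same joint posterior a sampler with explicit latent
coordinates would target.  Fits on data with no missingness return empty
imputation records.

### Sampling backend and diagnostics

All non-conjugate models are sampled with an affine-invariant ensemble
(emcee) using differential-evolution moves (80% DE, 20% snooker), which mix
much faster than the stretch move on these correlated posteriors.  Parameters
are transformed to the unconstrained scale (log for scales, tanh for ρ, logit
for probabilities, −1 − eᵘ for the upper-truncated κ) with Jacobians included.
Walkers initialize inside the typical set — least-squares solutions jittered
by twice their standard errors for regression coefficients, observed moments
for group means and scales, prior draws where the data carry no information.
Initializing with spread proportional to coefficient *magnitudes* instead
strands walkers in a large-residual-variance mode and was a genuine failure
mode during development; the standard-error-scaled jitter avoids it.

Post-warmup chains keep 800–1250 steps per walker (thinned evenly down to the
requested M), chosen so that split-R̂ ≤ 1.05 and bulk ESS ≥ 400 at the default
study sizes; both gates warn — never silently pass — when violated.  Walkers
are treated as chains for R̂/ESS; because ensemble walkers interact, these ESS
values are mildly optimistic, which the gate thresholds absorb.  The BsNmN
likelihood is compiled (numba) for speed; defaults (M = 2000 with 1000-step
warmup for the growth study, M = 5000 for the newborn study) follow the
analysis settings the models were designed around, and the test suite runs
scaled-down versions (M = 1000, S = 1000, n = 900, 20 replicates) as its
replication study.

## Derivations f

`log_bmi` and `sum_outcome` are exact closed forms.  Microcephaly is "head
circumference more than 2 standard deviations below the sex- and
gestational-age-specific average", with *strictly below* −2 on the z-score.
The reference average is a quadratic curve `HCReference` (intercept, sex
shift, linear and quadratic gestational-age terms; default coefficients
33.912, −0.450, 0.399, −0.016 cm — a plausible term-newborn population) with
a constant reference sd.  This is a parametric stand-in for tabulated newborn
growth standards: the published standards are an external resource and the
method is agnostic to the particular f, so the package does not reproduce
them.  No value for the standards' reference sd is published alongside the
curve; the default is 1.3 cm, and the synthetic generator uses the same value
for its non-affected scale so that the textbook 2.28% healthy-classification
rate holds by construction.  Both the curve and the sd are configurable.

## Conditional-risk propagation

For downstream models that need Pr(Y=1 | a patient's observed source values),
the per-draw source banks from g-computation step two are reused: rows
matching the observed binary values exactly and each observed continuous
value within ±ε are selected (defaults: ε = 0.25 cm for head circumference;
at least 50 matches expected at S = 5000), the conditioned columns are pinned
to the exact observed values, and f is averaged over the G_m matches.  Draws
with G_m below the threshold are flagged; an empty match yields a missing
value with guidance to raise S or ε rather than a silent zero.

## Comparator methods

* **Complete-case**: drop every row with any missing entry (idempotent;
  an empty result warns instead of crashing), then fit the analysis model.
* **Chained-equations imputation (SVL / on-the-fly)**: missing sources are
  imputed one variable at a time from Bayesian univariate conditionals —
  linear-Normal with the Jeffreys-prior conjugate draw for continuous
  variables, logistic with an asymptotic-Normal parameter draw (ridge
  fallback under separation) for binaries — and the derived outcome is
  recomputed from the current sources after every source update, so each of
  the K completed datasets satisfies the derivation exactly.  Imputation is
  *proper* throughout (parameters drawn, then data drawn); deterministic
  point imputation is not available.  Defaults: K = 50 datasets, 10 cycles.
  Predictors for a source variable are the other sources plus the
  explanatory variables; the derived outcome is excluded there because it is
  a deterministic function of the variable being imputed (and is missing
  exactly when that variable is), but it *is* a predictor when imputing
  explanatory variables — the on-the-fly scheme.  Optional per-variable
  bounds squeeze predictive draws into a derivation's validity window
  (gestational age needs this).
* **Pooled-posterior ("three-step") inference**: fit the analysis model on
  each completed dataset and mix all K·M draws; no combining rules.
  Datasets failing the convergence gate are excluded with a warning; more
  than K/2 failures aborts.

Derived-variable-level (DVL) and joint-Normal ("just another variable", JAV)
imputation are documented comparators in the field but are not implemented;
JAV in particular is known to behave badly for binary-outcome analyses.

## Synthetic studies

The generators define the package's study conditions and every test runs on
them; none reproduces an external dataset row-for-row.

* **Toy**: two groups (ζ = 0.5), bivariate-Normal sources, Y = Z1 + Z2,
  10% missing completely at random per variable.  The printed eight-row
  worked-example table ships as a constant.
* **Growth study**: n = 537 boys, ages uniform on [1, 18] years, 9% city
  membership, log-height/log-weight from the bivariate model (defaults chosen
  to reproduce realistic growth: ~80 cm / 10 kg at age 1 to ~180 cm / 70 kg at
  18, logBMI rising from ~15.8 to ~20.7 kg/m², residual correlation 0.5).
  Missingness is a calibrated *pattern* mechanism: height unmeasured with
  probability 18/537, weight additionally unmeasured for 2/18 of those, the
  city flag for 1/537 — giving 18/2/1 expected missing values and ≈19
  incomplete rows, with weight-missingness nested in height-missingness.
  The implied true group contrast is γ₁ − 2α₁ + (γ₃ − 2α₃)·E(A) = 0.01.
* **Newborn study**: n = 1800 newborns with sex/ga/hc from the BsNmN law.
  Default truth: μ = 0, σ = 2.5, ω = −2.5 (left-skewed gestational ages),
  non-affected curve equal to the reference with scale 1.3 cm, affected
  fraction 1 − q = 0.106 with shift κ = −6.0 cm and scale 2.5 cm (severe
  congenital deficits of several centimetres; the deep, well-separated
  affected component is what a single-Normal imputation model cannot
  represent) — giving a generating risk θ ≈ 11.7% (recomputed by Monte
  Carlo, never hard-coded).
  Missingness: sex 10% completely at random; gestational age missing more
  often for small head circumferences (logistic slope −0.4 per cm below
  33.4 cm); head circumference missing more often at late gestational age
  (slope +0.8 per week above 39).  Slopes and intercepts are calibrated
  (sweep script in `scripts/calibrate_missingness.py`) so ≈1019/1800 rows
  are complete, complete-case analysis lands low and single-Normal SVL
  imputation lands high — the bias structure the study conditions call for.
  Because the small-hc rows preferentially lose their gestational age, the
  complete-case subset is depleted of affected newborns and complete-case
  analysis is biased low — while SVL imputation with linear-Normal
  conditionals, unable to represent the mixture tail, lands high.  Rows that
  would lose all three measurements are redrawn so every newborn has at
  least one observed value.

What the generators do *not* emulate: measurement error, preferential
sampling, gestational-age digit preference, sex-specific reference sds, or
any covariate structure beyond the declared model — so passing tests certify
the estimation machinery under the assumed models, not robustness to
real-data violations of them.

## Numerical choices and degenerate inputs

Observed derived values are validated against f at 10⁻⁸ relative tolerance
(f may involve logs of measured values, so exact equality is wrong).
Likelihood underflow guards floor densities at 10⁻³⁰⁰; a quadrature
normalizer below that rejects the walker position.  The ga quadrature grid is
61 points (0.35-week spacing; halving the spacing moves log-likelihoods by
<10⁻³).  Conditional-risk matching uses half-open float equality for binary
conditions and ±ε for continuous ones.  Empty tables are legal inputs for
prior-only fits; all-missing rows are rejected at load time naming the row.

## Known limitations

The ensemble sampler's ESS diagnostics are approximate (interacting walkers);
the BsNmN posterior for (q, κ, ζ₂) is only weakly identified at moderate n,
which widens — but does not bias — the risk posterior; the quadrature
marginalization assumes the ga window truly bounds the support; and the
chained-equations comparator inherits the usual incompatibility between its
linear-Normal conditionals and the mixture data-generating process (which is
precisely the phenomenon the integrated model is built to avoid).
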