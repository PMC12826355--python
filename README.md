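# bgcomp — Bayesian g-computation for derived outcomes with missing sources

Many study outcomes are *derived* variables: deterministic functions of one or
more measured source variables.  logBMI is derived from height and weight;
newborn microcephaly status is derived from sex, gestational age and head
circumference via a z-score against growth standards.  When source variables
are partially missing, the usual toolbox — complete-case analysis, or
multiple imputation followed by a separate Bayesian analysis — either wastes
data, risks bias under informative missingness, or splits the problem into
two steps whose assumptions can silently disagree.

`bgcomp` implements the fully integrated alternative for analysts in
biostatistics and epidemiology: specify **one** generative model for the
source variables, treat the missing entries as part of the joint posterior,
and obtain posterior draws of any estimand by Monte Carlo **g-computation**
through the derivation f, with no analytic mapping from source-model
parameters to the estimand required.

## The method

Let W = (W_source, W_expl) be the p source and q explanatory variables,
Y = f(W_source) the derived outcome, and the estimand

θ = g( E*₁{E(Y | W_expl)}, …, E*_D{E(Y | W_expl)} )

a combination of conditional outcome expectations over D target populations
(possibly defined through unknown parameters γ_d).  The algorithm:

1. Draw M samples of (φ_source, W_expl^mis) from their joint posterior given
   the observed data — the source model is fitted with missing binaries
   marginalized analytically and missing continuous entries marginalized via
   the model's marginal laws, then imputed per draw from their exact full
   conditionals.
2. For each draw m and population d: draw γ_d[m] if needed; forward-simulate
   S iid source rows from the fitted conditional law; apply f row-wise;
   average to approximate E*_d{E(Y|W_expl)}[m].
3. Combine the D averages by g to obtain θ[m]; summarize the M draws by the
   posterior median and the equal-tailed 95% credible interval.

All uncertainty — parameters, imputations, and the inner Monte Carlo error —
propagates into the posterior of θ.  Closed-form estimand mappings (where a
model admits one) are provided both as fast paths and as oracles that the
g-computation engine is tested against.

Five source models ship with the package: a two-group bivariate-Normal toy
model; a univariate-Normal outcome regression; a correlated
log-height/log-weight growth model; a conjugate Bernoulli risk model; and a
Bernoulli(sex) + truncated-skew-Normal(gestational age) +
mixture-Normal(head circumference) newborn model.  Chained-equations multiple
imputation (source-level, with on-the-fly recomputation of the derived
outcome) plus pooled-posterior inference, and complete-case analysis, are
built in as comparators.  See `docs/methods.md` for models, priors,
numerical choices and limitations.

## Worked example

Estimate the microcephaly risk from a synthetic newborn study in which 43% of
rows have at least one of sex, gestational age or head circumference missing
— and the missingness is informative (small heads lose their gestational
age):

```python
import numpy as np
from bgcomp import (
    gen_microcephaly, fit_bsnmn, gcompute, fit_bernoulli, complete_cases,
    microcephaly_spec, EstimandSpec, PopulationSpec,
)

table, truth = gen_microcephaly(n=1800, seed=1)
print(f"generating risk: {100 * truth['theta']:.2f}%")

fit = fit_bsnmn(table, M=2000, seed=1, warmup=700)          # integrated model
theta = gcompute(fit, [PopulationSpec(index=1)], EstimandSpec.identity(),
                 microcephaly_spec(), S=2000, seed=1, table=table)
s = theta.summary()
print(f"integrated:    {100 * s['median']:.2f}% "
      f"[{100 * s['ci_low']:.2f}, {100 * s['ci_high']:.2f}]")

cc = fit_bernoulli(complete_cases(table), M=5000, seed=1)    # complete cases
print(f"complete-case: {100 * np.median(cc.params['theta']):.2f}%")
```

Output:

```
generating risk: 11.68%
integrated:    12.07% [10.10, 14.25]
complete-case: 5.63%
```

The complete-case estimate is badly biased low — the mechanism preferentially
removes the gestational ages of small-headed (affected) newborns, so the
complete rows under-represent cases — while the integrated model's credible
interval covers the generating risk.

The same pipeline is scriptable from the shell:

```bash
bgcomp simulate -c sim.yaml -o data.csv        # table + truth sidecar
bgcomp fit      -c fit.yaml -t data.csv -o fit # draws + summary + diagnostics
bgcomp estimate -c est.yaml -d fit.draws.csv -t data.csv -o theta.json
bgcomp compare  -c cmp.yaml -t data.csv -o comparison.json
```

where the YAML configs name the generator/model and the M, S, K, seed
settings; every run writes a manifest (config hash, seed, versions) that
suffices to re-run it exactly.

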