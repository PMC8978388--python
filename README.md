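# ghsurv

Bayesian survival analysis of comorbidity effects in three steps, for
cancer epidemiologists and applied biostatisticians working with
registry-style cohorts (right-censored follow-up, one continuous
covariate such as age, a panel of binary comorbidity indicators).

1. **Variable selection.** A censored log-normal AFT model
   `log o_i = x_i'β_γ + ε_i`, `ε_i ~ N(0, σ²)`, is scanned over inclusion
   vectors γ with either a g-Zellner prior
   `α_j ~ N(0, g_L n/(x_j'x_j))` or a non-local product-moment prior
   `α_j ~ (α_j²/g_M) N(0, g_M)` on the scaled coefficients `α = β/σ`, a
   Beta-Binomial prior on model size, and Laplace-approximated marginal
   likelihoods. Covariates with posterior inclusion probability
   PIP > 0.5 are selected.
2. **Hazard regression.** The selected covariates enter a general-hazards
   model `h(t|z) = h0(t e^{z̃'θ̃}|ξ) e^{z'θ}` — containing PH (θ̃=0),
   AH (θ=0) and AFT (θ̃=θ) as special cases — with Power Generalised
   Weibull, log-logistic or log-normal baselines, half-Cauchy/wide-normal
   priors, ensemble MCMC, and candidate models compared by posterior
   model probabilities from bridge-sampled marginal likelihoods.
3. **Effect measures.** From the posterior draws: conditional and
   marginal (counterfactual) survival functions CS/MS, the conditional
   effect PPCE = CS0−CS1, attributable survival
   PPAS = π_r(1−CS1/CS0), attributable risk
   PPAR = π_r(CS0−CS1)/[π_r(CS0−CS1)+1−CS0], marginal effect
   PPME = MS0−MS1, and restricted mean survival time
   RMST(t*) = ∫₀^{t*} MS dt, each with pointwise 95% credible bands.

See `docs/methods.md` for model details, priors, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from ghsurv import (AFTVariableSelection, GeneralHazardsModel,
                    GHParameters, BaselineParams, SimulationConfig,
                    simulate_dataset, compare_gh_models, SurvivalDataset)

# a synthetic 600-subject cohort: age plus one comorbidity (prevalence
# 30%) that raises the hazard (true log-HRs 0.7 and 0.8), PGW baseline,
# administrative censoring at 6 years
cfg = SimulationConfig(
    n=600, prevalences=(0.3,), continuous_covariates=1,
    true_params=GHParameters(BaselineParams("PGW", (5.0, 1.2, 0.9)),
                             np.zeros(0), np.array([0.7, 0.8])),
    structure="PH", horizon=6.0, seed=42)
data = simulate_dataset(cfg)

# Step 1: which covariates matter?
sel = AFTVariableSelection.from_survival(data).fit(coefficient_prior="mom")
print(sel.pips.round(3))

# Step 2: fit a PH model with PGW baseline on the selected covariates
model = GeneralHazardsModel(data, structure="PH", family="PGW")
res = model.fit(seed=1)
print(res.summary().round(3))

# Step 3: effect of the comorbidity on population survival
curve = res.ppme(k=1)                      # marginal effect over time
print(curve.to_frame().iloc[[10, 50, 99]].round(3))
print(res.rmst(6.0, k=1, r=0), res.rmst(6.0, k=1, r=1))
```

Output (abridged):

```
age        1.0
comorb1    1.0
dtype: float64

            mean     HR  CI 2.5%  CI 97.5%  P(HR>1|Data)
parameter
eta        2.902    NaN    1.843     4.996           NaN
nu         1.468    NaN    1.285     1.657           NaN
delta      1.663    NaN    0.933     2.439           NaN
age        0.760  2.139    1.939     2.337           1.0
comorb1    0.841  2.318    1.948     2.723           1.0

     time  estimate  lower  upper
10  0.606     0.091  0.068  0.113
50  3.030     0.242  0.194  0.285
99  6.000     0.184  0.149  0.217

(3.465, 3.319, 3.615) (2.306, 2.137, 2.487)
```

Both PIPs are 1 (both covariates clearly matter), the posterior means
recover the true log-hazard ratios 0.7/0.8 (HRs ≈ 2.1–2.3 per
standardised unit), the marginal survival difference attributable to the
comorbidity peaks around 24 percentage points mid-follow-up, and the
comorbidity costs about 1.2 life-years over the 6-year horizon
(RMST 3.47 vs 2.31 years, with 95% intervals alongside).

## Command line

```bash
ghsurv simulate --out cohort.csv --n 600 --theta 0.6,0.8 --seed 1
ghsurv select cohort.csv --out pips.csv
ghsurv compare cohort.csv --covariates age,comorb1
ghsurv fit cohort.csv --covariates age,comorb1 --family PGW --out draws.csv
ghsurv effects cohort.csv --draws draws.csv --covariate comorb1
ghsurv run config.yaml     # full, optionally stratified, three-step pipeline
```

`ghsurv run` reads a YAML config (input table, column roles, optional
stratum column, priors, candidate models, MCMC and effect-measure
settings), writes per-stratum PIP reports, model-comparison tables,
posterior summaries, effect-curve CSVs and a manifest of seeds and
decisions.

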