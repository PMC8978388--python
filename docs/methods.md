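# Methods

`ghsurv` implements a three-step Bayesian workflow for quantifying the
effect of comorbidities (binary exposures) on the survival of a patient
cohort with right-censored follow-up: (1) Bayesian variable selection in a
censored accelerated-failure-time model, (2) parametric general-hazards
regression with formal model comparison, (3) posterior predictive effect
measures with credible bands. This note records the models, the numerical
choices, and the limits of what the test suite demonstrates.

## Step 1 — variable selection in the censored AFT model

**Model.** Log event times follow `log o_i = x_i' beta_gamma + eps_i`,
`eps_i ~ N(0, sigma^2)`, with right censoring at `c_i`; the observed
log-time is `y_i = min(log o_i, log c_i)` with event indicator `delta_i`.
The inclusion vector `gamma` indexes the `2^p` candidate models. In the
reparameterisation `alpha = beta/sigma`, `tau = 1/sigma` the censored
log-likelihood

    l(alpha, tau) = -(n_o/2) log(2 pi / tau^2)
                    - 1/2 sum_{delta=1} (tau y_i - x_i' alpha)^2
                    + sum_{delta=0} log Phi(x_i' alpha - tau y_i)

is jointly concave in `(alpha, tau)` (verified by randomized chord checks
in the tests), which is what makes the mode-finding for the Laplace
approximation reliable.

**Priors.** Two coefficient priors, applied per included column:

* g-Zellner (`zellner`): `alpha_j ~ N(0, g_L n / (x_j'x_j))` — a local
  prior; ordinary shrinkage.
* product-moment non-local (`mom`): `alpha_j ~ (alpha_j^2/g_M) N(0, g_M)`
  — vanishes at zero, so models carrying a covariate whose effect is
  nearly zero are actively penalised, sharpening selection.

`tau` carries `pi(tau) = 2 tau^-3 IG(tau^-2; a_tau/2, b_tau/2)`, which
collapses to `pi(tau) ∝ tau^(a_tau-1) exp(-b_tau tau^2 / 2)` — proper for
all positive hyperparameters (normalisation verified by quadrature).
Model size carries a Beta-Binomial(`a1`, `b1`) prior whose mass at each
size is divided equally among the models of that size, so the prior sums
to 1 over the model space; `a1 = b1 = 1` (uniform on size) is the
default since no particular size is favoured a priori.

**Hyperparameter elicitations.** Two schemes, selected by `elicitation`:

* `unit_information` (default): every coefficient's prior variance is set
  to 1 on the standardised design (per-column `g_L = x_j'x_j / n`;
  `g_M = 1`) — a prior carrying roughly one observation of information.
  This mirrors a unit-information option exposed by selection software
  whose exact internal mapping is not published; the variance-1 reading
  is an approximation, and the selection results should be (and in the
  acceptance simulations are) robust across the two schemes.
* `fixed`: `g_M = 0.192`, `g_L = 1`, `a_tau = b_tau = 1`, the published
  recommendation that assigns low prior probability to effects with
  `e^|beta| < 1.15` — hazard-ratio-scale changes too small to matter
  clinically.

**Computation.** Each model's integrated likelihood `p(y|gamma)` is a
Laplace approximation at the posterior mode of `(alpha_gamma, tau)`:
quasi-Newton (L-BFGS-B) with the analytic gradient, started from the
least-squares fit on event rows (non-local-prior coefficients are started
away from 0 since that prior vanishes there), with jittered restarts on
failure; the Hessian is a central finite difference of the analytic
gradient. `log p(y|gamma) = f(mode) + (d/2) log 2pi - (1/2) log det(-H)`
with `d` the full optimised dimension (intercept + included coefficients
+ tau). An intercept is always included, never selected over, and always
carries the Zellner-form prior; continuous covariates are standardised
(binary 0/1 columns never transformed) so the dispersion parameters mean
the same thing across columns. The approximation is checked against 1-D
and 2-D adaptive quadrature in the tests (gaps < 0.05 and < 0.1 on the
log scale).

Posterior model probabilities are `exp(log p(y|gamma) + log pi(gamma))`
normalised by log-sum-exp; exhaustively over all `2^p` models for
`p <= 15` by default (configurable — beyond that the cost of `2^p` mode
findings dominates), otherwise by a Gibbs scan over inclusion indicators
with Rao-Blackwellised PIPs and renormalisation over the visited models.
Rank-deficient submodels get probability zero with a warning. The PIP of
covariate j is the total probability of models containing it; the
selected set is `{j : PIP_j > 0.5}` (strict inequality).

## Step 2 — general-hazards regression

**Model.** The hazard for subject i is

    h(t | z_i) = h0(t exp(z~_i' theta~) | xi) exp(z_i' theta)

with baseline `h0` from a parametric family. Setting `theta~ = 0` gives
proportional hazards (PH), `theta = 0` accelerated hazards (AH), and
`theta~ = theta` with shared covariates the AFT model. The cumulative
hazard has the closed form `exp(z'theta - z~'theta~) H0(t exp(z~'theta~))`
(change of variables; verified against adaptive quadrature to 1e-6
relative), so the censored likelihood needs no numerical integration.

**Baselines.** Power Generalised Weibull `H0 = [1+(t/eta)^nu]^(1/delta) - 1`
(increasing, decreasing, unimodal and bathtub hazard shapes), log-logistic
`H0 = log(1+(t/eta)^nu)`, log-normal via the normal ccdf of `log t`, plus
gamma and generalised gamma. All evaluated in log space
(`log(1+(t/eta)^nu)` via `logaddexp`) to avoid overflow at large times or
extreme shapes. `t = 0` with a decreasing-hazard shape returns the correct
`+inf` limit; likelihood code never evaluates the hazard at exactly 0
because observed times are strictly positive by construction. By default
binary comorbidities enter only the hazard level (no time-dependent effect
for a yes/no condition); continuous covariates (age) may enter both. Age
is standardised before fitting (switchable), so its coefficient is per
standard deviation.

**Priors and sampling.** Half-Cauchy(scale 2.5) on each positive baseline
parameter and N(0, 10^2) on every regression coefficient — weakly
informative defaults for time scales of a few years; both scales are
configurable. Sampling runs on the unconstrained scale (log-transformed
positive parameters, Jacobian included) with an affine-invariant ensemble
sampler (emcee; differential-evolution + snooker moves), 32 walkers by
default, initialised in a tight ball around the posterior mode found by
direct optimisation. Defaults: 1500 warmup ensemble steps, then at least
400 kept steps thinned to 2000 pooled draws. Convergence is monitored by
rank-normalised R-hat and ESS computed across walker subgroups (a
practical stand-in for independent chains, since walkers interact);
results are flagged when R-hat > 1.01 or ESS < 100, and flagged fits are
excluded from model comparison.

**Marginal likelihood and model comparison.** The marginal likelihood of
each candidate (structure, family) pair is estimated by the iterative
optimal-bridge estimator: half the posterior draws moment-match a
Gaussian proposal on the unconstrained scale, the other half plus fresh
proposal draws enter the bridge fixed-point iteration (tolerance 1e-10,
max 1000 iterations), with the log ratios centred at their maximum so the
iteration runs near magnitude one. The standard error uses the iid
asymptotic formula; the estimator is validated against a conjugate-normal
closed form (within 0.05) and by reseeded self-consistency. Candidates
are compared through posterior model probabilities under equal prior
mass (configurable).

**Summaries.** Coefficient tables report the posterior mean, the hazard
ratio as `exp(posterior mean)` (matching how published coefficient/HR
pairs relate), 95% intervals as the 2.5%/97.5% quantiles of the
exp-transformed draws, and `P(HR>1|Data)` as the fraction of draws with a
positive coefficient. Whether published HR intervals are quantiles of
exp(draws) or exp of coefficient quantiles is not documented; the two are
numerically near-identical here, and the quantile-of-draws convention was
chosen as the more directly posterior-predictive one.

## Step 3 — posterior predictive effect measures

For a binary covariate k at level r, with posterior draws j = 1..M:

* conditional survival `CS(t,k,r)`: average predictive survival
  `exp(-H(t|z_i))` over the observed subgroup `z_ik = r` and over draws;
* marginal survival `MS(t,k,r)`: the whole-cohort counterfactual with
  every subject's `z_ik` set to r (the same-named time-level column, if
  present, is set too);
* `PPCE = CS0 - CS1`, `PPAS = pi_r (1 - CS1/CS0)`,
  `PPAR = pi_r (CS0-CS1) / [pi_r (CS0-CS1) + 1 - CS0]`,
  `PPME = MS0 - MS1`, and `RMST(t*,k,r)`, the area under MS up to t*
  (composite trapezoid, 1000-point grid per draw).

`pi_r` is the empirical prevalence of level 1 in the analysis data; no
standardisation weights are applied. Each measure is computed per draw
(population-averaged within the draw) and then summarised: the mean
across draws reproduces the double-sum definitions exactly by linearity,
and pointwise 2.5%/97.5% quantiles across draws give the credible band
(the publications showing such bands do not define them; the per-draw
construction is the natural Monte-Carlo one). Degenerate points:
`CS0 = 0` in PPAS uses the limiting value `pi_r` with a warning; a zero
PPAR denominator (t = 0) is defined as 0. Requesting a measure for a
continuous column is an error, not an implicit dichotomisation. Default
grid: 100 equally spaced points from 0 to the longest observed follow-up.

**A note on PPAR's shape.** PPAR is sometimes described as increasing
toward a plateau. Algebraically it rises instantly from 0 to roughly
`pi_r(HR-1) / (pi_r(HR-1) + 1)` as t leaves 0, varies slowly (a plateau)
while substantial survival remains, and decays to 0 as the unexposed
cumulative incidence `1 - CS0` approaches 1 — including under parameter
configurations matching published comorbidity analyses. The end-to-end
tests therefore assert the positive-plateau shape over the follow-up
window rather than global monotonicity.

## Synthetic data

The generator emulates registry-like cohorts: a standard-normal "age"
column plus independent Bernoulli comorbidity columns with prevalences
defaulting to (0.252, 0.185, 0.145, ...) — a diabetes/COPD/heart-failure
mix typical of early-stage colorectal cancer cohorts, padded with rarer
conditions down to 2% — and administrative censoring at a 6-year horizon
(8 years is typical for lung-cancer follow-up). Event times are exact
draws from the GH model by cumulative-hazard inversion:
`T = exp(-a) H0^{-1}(E exp(a-b))` with `E ~ Exp(1)`, `a = z~'theta~`,
`b = z'theta` — validated by a KS test against Exp(1) in the null case
and by Kaplan-Meier agreement with the model survival (< 0.02 sup
distance at n = 10000). A single integer seed drives covariates, event
times, then censoring, in that order, so datasets are bit-reproducible.
The default true model for benchmark cohorts is PGW(5.0, 1.2, 0.9) —
median survival of a few years with mild non-monotone hazard, giving
event fractions around 60-75% at the 6-year horizon, inside the 30-80%
range typical of these registries.

The selection benchmark draws standard-normal candidate covariates,
log-normal AFT times with a known active set, and administrative
censoring at the empirical quantile of the event times that realises the
requested censoring rate to within 1/n.

What the generator does **not** emulate: correlated comorbidities are off
by default (marginal prevalences only; a Gaussian-copula knob exists for
robustness checks — real comorbidities co-occur), missing data and
imputation, delayed entry, and informative censoring. Passing tests
demonstrate correctness of the computations and frequentist operating
characteristics under the generating model — not robustness to the
messiness of real registry data.

## Problem sizes in tests and the acceptance script

Simulation-based checks use the cohort sizes above (n = 500-600, p = 10,
10-20 replicates; MCMC runs of 1000-1500 warmup steps with ~1200-2000
pooled draws), sizes at which the operating characteristics stabilise
while a full run stays in the minutes range on a single core.

## Known limitations

* The Gibbs model-space search reports posteriors renormalised over
  visited models only; unvisited high-probability models are unaccounted
  for (PIPs, being Rao-Blackwellised, are less affected).
* The Laplace approximation evaluates one mode; under the non-local prior
  with a near-zero effect the integrand is bimodal (±) and the single-mode
  approximation slightly underestimates that model's marginal — which only
  further penalises negligible effects, in the prior's intended direction.
* Walker-subgroup R-hat/ESS are conservative heuristics, not
  independent-chain diagnostics.
* No left truncation, time-varying covariates, competing risks, frailties
  or excess-hazard modelling; no age-standardised effect measures.
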