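"""Bayesian variable selection for the censored log-normal AFT model.

The selection model assumes log event times follow a log-linear regression

    log(o_i) = x_i' beta_gamma + eps_i,   eps_i ~ N(0, sigma^2)

with right censoring, where the inclusion indicator gamma picks which of
the p candidate covariates enter.  Working in the reparameterisation
alpha = beta / sigma, tau = 1 / sigma makes the censored log-likelihood

    l(alpha, tau) = -(n_o/2) log(2 pi / tau^2)
                    - 1/2 sum_{events} (tau y_i - x_i' alpha)^2
                    + sum_{censored} log Phi(x_i' alpha - tau y_i)

jointly log-concave, so the integrated likelihood p(y | gamma) of each
model is well approximated by a Laplace approximation at the posterior
mode.  Two coefficient priors are supported:

* ``zellner`` (pi_L): alpha_j ~ N(0, g_L * n / (x_j' x_j)) — a g-prior.
* ``mom`` (pi_M): alpha_j ~ (alpha_j^2 / g_M) N(alpha_j; 0, g_M) — a
  non-local product-moment prior that vanishes at zero and therefore
  penalises small effects.

The precision root tau carries the prior pi(tau) = 2 tau^-3 IG(tau^-2;
a_tau/2, b_tau/2), and model size carries a Beta-Binomial prior whose mass
at each size is split equally among the models of that size.  Posterior
model probabilities follow by normalising exp(log marginal + log model
prior) over the model space (exhaustively for moderate p, otherwise by a
Gibbs scan over inclusion indicators), and each covariate's posterior
inclusion probability (PIP) is the total probability of the models that
contain it.  Covariates with PIP > 0.5 form the selected set passed to the
hazard-regression stage.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .gh import SurvivalDataset

__all__ = [
    "SelectionData",
    "SelectionPrior",
    "SelectionResults",
    "AFTVariableSelection",
    "aft_loglik",
    "aft_loglik_grad",
    "log_tau_prior",
    "log_parameter_prior",
    "log_model_prior",
    "laplace_log_marginal",
    "compute_pips",
    "select_variables",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data container


@dataclass
class SelectionData:
    """Observed log-times, censoring indicators and the candidate design.

    ``y`` holds y_i = min(log o_i, log c_i); ``X`` the n x p candidate
    matrix (no intercept column).  The design restricted to event rows
    must have full column rank for every evaluated submodel.
    """

    y: np.ndarray
    status: np.ndarray
    X: np.ndarray
    names: Sequence[str] = ()

    def __post_init__(self):
        self.y = np.asarray(self.y, float).ravel()
        self.status = np.asarray(self.status).astype(int).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, float))
        if self.X.shape[0] != self.y.size or self.status.size != self.y.size:
            raise ValueError("inconsistent number of rows")
        if self.status.sum() < 1:
            raise ValueError("at least one event is required")
        if not self.names:
            self.names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @classmethod
    def from_survival(cls, data: SurvivalDataset) -> "SelectionData":
        if np.any(data.times <= 0):
            raise ValueError("times must be strictly positive to take logs")
        return cls(np.log(data.times), data.status, data.Z, list(data.names))


@dataclass(frozen=True)
class SelectionPrior:
    """Hyperparameters of the coefficient, precision and model priors.

    ``elicitation='unit_information'`` sets every coefficient's prior
    variance to 1 on the standardised design (g-prior scale chosen per
    column so g * n / (x_j'x_j) = 1; g_M = 1), a prior worth roughly one
    observation.  ``'fixed'`` uses g_M = 0.192, g_L = 1, penalising
    effects with e^|beta| < 1.15 as practically irrelevant.
    """

    coefficient_prior: str = "mom"  # 'zellner' (pi_L) or 'mom' (pi_M)
    elicitation: str = "unit_information"  # or 'fixed'
    g_L: float = 1.0
    g_M: float = 0.192
    a_tau: float = 1.0
    b_tau: float = 1.0
    a1: float = 1.0
    b1: float = 1.0

    def __post_init__(self):
        if self.coefficient_prior not in ("zellner", "mom"):
            raise ValueError("coefficient_prior must be 'zellner' or 'mom'")
        if self.elicitation not in ("unit_information", "fixed"):
            raise ValueError("elicitation must be 'unit_information' or 'fixed'")
        for nm in ("g_L", "g_M", "a_tau", "b_tau", "a1", "b1"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")


# ---------------------------------------------------------------------------
# likelihood and priors


def aft_loglik(alpha, tau, y, status, X) -> float:
    """Censored AFT log-likelihood in the (alpha, tau) parameterisation."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    alpha = np.atleast_1d(np.asarray(alpha, float))
    y = np.asarray(y, float)
    status = np.asarray(status)
    X = np.atleast_2d(np.asarray(X, float))
    eta = X @ alpha
    ev = status == 1
    n_o = int(ev.sum())
    resid = tau * y[ev] - eta[ev]
    ll = -0.5 * n_o * np.log(2.0 * np.pi / tau**2) - 0.5 * np.sum(resid**2)
    if (~ev).any():
        ll += np.sum(stats.norm.logcdf(eta[~ev] - tau * y[~ev]))
    return float(ll)


def aft_loglik_grad(alpha, tau, y, status, X) -> Tuple[np.ndarray, float]:
    """Analytic gradient of :func:`aft_loglik` w.r.t. (alpha, tau)."""
    alpha = np.atleast_1d(np.asarray(alpha, float))
    eta = X @ alpha
    ev = status == 1
    n_o = int(ev.sum())
    resid = tau * y[ev] - eta[ev]
    g_alpha = X[ev].T @ resid
    g_tau = n_o / tau - resid @ y[ev]
    if (~ev).any():
        m = eta[~ev] - tau * y[~ev]
        # inverse Mills ratio phi/Phi, stable in the left tail
        rho = np.exp(stats.norm.logpdf(m) - stats.norm.logcdf(m))
        g_alpha = g_alpha + X[~ev].T @ rho
        g_tau = g_tau - rho @ y[~ev]
    return g_alpha, float(g_tau)


def log_tau_prior(tau, a_tau: float = 1.0, b_tau: float = 1.0):
    """log pi(tau) with pi(tau) = 2 tau^-3 IG(tau^-2; a/2, b/2).

    Collapses to log pi(tau) = C + (a-1) log tau - (b/2) tau^2 with
    C = log 2 + (a/2) log(b/2) - lgamma(a/2).
    """
    tau = np.asarray(tau, float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    C = np.log(2.0) + 0.5 * a_tau * np.log(0.5 * b_tau) - special.gammaln(0.5 * a_tau)
    out = C + (a_tau - 1.0) * np.log(tau) - 0.5 * b_tau * tau**2
    return out if out.ndim else float(out)


def _coef_prior_spec(prior: SelectionPrior, col_ss: np.ndarray, n: int,
                     mom_mask: np.ndarray) -> Tuple[np.ndarray, float]:
    """Per-column Gaussian variances and the MOM dispersion.

    ``col_ss`` holds x_j'x_j of each design column (intercept first).
    Columns where ``mom_mask`` is False always use the Zellner form (the
    intercept is never penalised by the non-local prior).
    """
    if prior.elicitation == "unit_information":
        variances = np.ones_like(col_ss)
        g_M = 1.0
    else:
        variances = prior.g_L * n / col_ss
        g_M = prior.g_M
    return variances, g_M


def log_coef_prior(alpha, variances, mom_mask, g_M) -> float:
    """Log prior of a coefficient vector: Zellner columns are mean-zero
    normals; MOM columns get the extra alpha^2/g penalty factor."""
    alpha = np.atleast_1d(np.asarray(alpha, float))
    lp = 0.0
    zell = ~mom_mask
    if zell.any():
        v = variances[zell]
        lp += float(np.sum(stats.norm.logpdf(alpha[zell], scale=np.sqrt(v))))
    if mom_mask.any():
        a = alpha[mom_mask]
        with np.errstate(divide="ignore"):
            lp += float(
                np.sum(2.0 * np.log(np.abs(a)) - np.log(g_M)
                       + stats.norm.logpdf(a, scale=np.sqrt(g_M)))
            )
    return lp


def log_parameter_prior(alpha, tau, prior: SelectionPrior, col_ss, n,
                        mom_mask=None) -> float:
    """Joint log prior pi(alpha_gamma, tau) for an evaluated submodel.

    ``col_ss`` are the x_j'x_j of the columns matching ``alpha``;
    ``mom_mask`` marks which of them take the non-local prior when
    ``coefficient_prior='mom'`` (default: all of them).
    """
    alpha = np.atleast_1d(np.asarray(alpha, float))
    col_ss = np.atleast_1d(np.asarray(col_ss, float))
    if mom_mask is None:
        mom_mask = np.ones(alpha.size, bool)
    if prior.coefficient_prior == "zellner":
        mom_mask = np.zeros(alpha.size, bool)
    variances, g_M = _coef_prior_spec(prior, col_ss, n, mom_mask)
    return log_coef_prior(alpha, variances, mom_mask, g_M) + float(
        log_tau_prior(tau, prior.a_tau, prior.b_tau)
    )


def log_model_prior(p_gamma: int, p: int, a1: float = 1.0, b1: float = 1.0) -> float:
    """Beta-Binomial prior on model size, split equally among the
    C(p, p_gamma) models of that size:

        pi(gamma) = BetaBin(p_gamma; p, a1, b1) / C(p, p_gamma).
    """
    if not 0 <= p_gamma <= p:
        raise ValueError("model size out of range")
    log_betabin = (
        special.gammaln(p + 1)
        - special.gammaln(p_gamma + 1)
        - special.gammaln(p - p_gamma + 1)
        + special.betaln(p_gamma + a1, p - p_gamma + b1)
        - special.betaln(a1, b1)
    )
    log_choose = (
        special.gammaln(p + 1)
        - special.gammaln(p_gamma + 1)
        - special.gammaln(p - p_gamma + 1)
    )
    return float(log_betabin - log_choose)


# ---------------------------------------------------------------------------
# Laplace approximation


class LaplaceError(RuntimeError):
    pass


def _neg_logpost(psi, y, status, X, variances, mom_mask, g_M, a_tau, b_tau):
    alpha, tau = psi[:-1], psi[-1]
    if tau <= 0:
        return np.inf, np.zeros_like(psi)
    eta = X @ alpha
    ev = status == 1
    n_o = int(ev.sum())
    resid = tau * y[ev] - eta[ev]
    ll = -0.5 * n_o * np.log(2.0 * np.pi / tau**2) - 0.5 * resid @ resid
    g_alpha = X[ev].T @ resid
    g_tau = n_o / tau - resid @ y[ev]
    if (~ev).any():
        m = eta[~ev] - tau * y[~ev]
        ll += np.sum(stats.norm.logcdf(m))
        rho = np.exp(stats.norm.logpdf(m) - stats.norm.logcdf(m))
        g_alpha = g_alpha + X[~ev].T @ rho
        g_tau = g_tau - rho @ y[~ev]
    # priors
    zell = ~mom_mask
    if zell.any():
        v = variances[zell]
        ll += -0.5 * np.sum(np.log(2 * np.pi * v)) - 0.5 * np.sum(alpha[zell] ** 2 / v)
        g_alpha[zell] += -alpha[zell] / v
    if mom_mask.any():
        a = alpha[mom_mask]
        if np.any(a == 0):
            return np.inf, np.zeros_like(psi)
        ll += np.sum(2.0 * np.log(np.abs(a))) - mom_mask.sum() * np.log(g_M)
        ll += -0.5 * mom_mask.sum() * np.log(2 * np.pi * g_M) - 0.5 * np.sum(a**2) / g_M
        g_alpha[mom_mask] += 2.0 / a - a / g_M
    ll += (a_tau - 1.0) * np.log(tau) - 0.5 * b_tau * tau**2
    ll += np.log(2.0) + 0.5 * a_tau * np.log(0.5 * b_tau) - special.gammaln(0.5 * a_tau)
    g_tau += (a_tau - 1.0) / tau - b_tau * tau
    grad = np.concatenate([g_alpha, [g_tau]])
    if not np.isfinite(ll):
        return np.inf, np.zeros_like(psi)
    return -ll, -grad


def _fd_hessian(fun_grad, psi, args):
    d = psi.size
    H = np.empty((d, d))
    for i in range(d):
        h = 1e-5 * (1.0 + abs(psi[i]))
        up = psi.copy()
        up[i] += h
        dn = psi.copy()
        dn[i] -= h
        gu = fun_grad(up, *args)[1]
        gd = fun_grad(dn, *args)[1]
        H[i] = (gu - gd) / (2.0 * h)
    return 0.5 * (H + H.T)


def laplace_log_marginal(
    y, status, X, prior: SelectionPrior, col_ss=None, mom_mask=None,
    start=None, model_label="model", n_restarts=3, rng=None,
) -> float:
    """Laplace approximation to log p(y | gamma) for one submodel.

    Maximises aft_loglik + log prior over (alpha, tau) by quasi-Newton with
    the analytic gradient, then applies

        log p(y|gamma) ~= f(mode) + (d/2) log(2 pi) - 1/2 log det(-H)

    with H the Hessian of the log-integrand at the mode (central finite
    differences of the gradient).
    """
    y = np.asarray(y, float)
    status = np.asarray(status).astype(int)
    X = np.atleast_2d(np.asarray(X, float))
    n, d_a = X.shape
    if col_ss is None:
        col_ss = np.einsum("ij,ij->j", X, X)
    col_ss = np.atleast_1d(np.asarray(col_ss, float))
    if mom_mask is None:
        mom_mask = np.ones(d_a, bool)
    if prior.coefficient_prior == "zellner":
        mom_mask = np.zeros(d_a, bool)
    variances, g_M = _coef_prior_spec(prior, col_ss, n, mom_mask)
    args = (y, status, X, variances, np.asarray(mom_mask, bool), g_M,
            prior.a_tau, prior.b_tau)

    if start is None:
        start = _default_start(y, status, X, mom_mask)
    rng = np.random.default_rng(0) if rng is None else rng

    psi0 = np.asarray(start, float)
    best = None
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(
            _neg_logpost, psi0, args=args, jac=True, method="L-BFGS-B",
            bounds=[(None, None)] * d_a + [(1e-8, None)],
            options={"maxiter": 500},
        )
        if res.success or np.linalg.norm(res.jac) < 1e-3 * (1 + abs(res.fun)):
            H = _fd_hessian(_neg_logpost, res.x, args)
            sign, logdet = np.linalg.slogdet(H)
            if sign > 0:
                cand = -res.fun + 0.5 * (d_a + 1) * np.log(2 * np.pi) - 0.5 * logdet
                if best is None or cand > best:
                    best = cand
        psi0 = np.asarray(start, float) + rng.normal(scale=0.3, size=d_a + 1)
        psi0[-1] = abs(psi0[-1]) + 0.05
        if np.asarray(mom_mask, bool).any():
            a = psi0[:-1][np.asarray(mom_mask, bool)]
            a[np.abs(a) < 0.15] = np.where(a[np.abs(a) < 0.15] >= 0, 0.15, -0.15)
            psi0[:-1][np.asarray(mom_mask, bool)] = a
        if best is not None and attempt >= 0:
            break
    if best is None:
        raise LaplaceError(f"mode finding failed for {model_label}")
    return float(best)


def _default_start(y, status, X, mom_mask):
    ev = status == 1
    Xo, yo = X[ev], y[ev]
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    dof = max(len(yo) - X.shape[1], 1)
    sigma = max(np.sqrt(resid @ resid / dof), 1e-2)
    tau0 = 1.0 / sigma
    alpha0 = beta * tau0
    mm = np.asarray(mom_mask, bool)
    if mm.any():
        a = alpha0[mm]
        small = np.abs(a) < 0.15
        a[small] = np.where(a[small] >= 0, 0.15, -0.15)
        alpha0[mm] = a
    return np.concatenate([alpha0, [tau0]])


# ---------------------------------------------------------------------------
# results object


@dataclass
class SelectionResults:
    """Posterior over the model space and per-variable PIPs."""

    names: Sequence[str]
    model_posteriors: Dict[Tuple[int, ...], float]
    pips: pd.Series
    prior: SelectionPrior
    exhaustive: bool
    log_marginals: Dict[Tuple[int, ...], float] = field(default_factory=dict)

    @property
    def top_model(self) -> Tuple[int, ...]:
        return max(self.model_posteriors, key=self.model_posteriors.get)

    def selected(self, threshold: float = 0.5) -> Tuple[int, ...]:
        """Inclusion indicator of the variables with PIP strictly above
        ``threshold`` (the PIP > 0.5 rule by default)."""
        return select_variables(self.pips.to_numpy(), threshold)

    def selected_names(self, threshold: float = 0.5) -> list:
        gamma = self.selected(threshold)
        return [n for n, g in zip(self.names, gamma) if g == 1]

    def top_models(self, k: int = 10) -> pd.DataFrame:
        items = sorted(self.model_posteriors.items(), key=lambda kv: -kv[1])[:k]
        rows = [
            {
                "model": "+".join(n for n, g in zip(self.names, gamma) if g) or "(null)",
                "size": int(sum(gamma)),
                "posterior_prob": prob,
            }
            for gamma, prob in items
        ]
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "PIP": self.pips,
                "selected": [g == 1 for g in self.selected()],
            }
        )

    def save_report(self, pip_path, models_path=None, top_k: int = 10) -> None:
        self.summary().to_csv(pip_path, index_label="variable")
        if models_path is not None:
            self.top_models(top_k).to_csv(models_path, index=False)


def compute_pips(model_posteriors: Dict[Tuple[int, ...], float], p: int) -> np.ndarray:
    """PIP_j = sum of posterior probabilities of the models with gamma_j=1."""
    pips = np.zeros(p)
    for gamma, prob in model_posteriors.items():
        pips += prob * np.asarray(gamma, float)
    return pips


def select_variables(pips, threshold: float = 0.5) -> Tuple[int, ...]:
    """Indicator of {j : PIP_j > threshold} (strict inequality)."""
    pips = np.asarray(pips, float)
    if np.any((pips < -1e-9) | (pips > 1 + 1e-9)):
        raise ValueError("PIPs must lie in [0, 1]")
    return tuple(int(v) for v in (pips > threshold))


# ---------------------------------------------------------------------------
# model


class AFTVariableSelection:
    """Variable-selection model for right-censored log-normal AFT data.

    Parameters
    ----------
    times, status : array-like
        Follow-up times (> 0, years) and event indicators (1 = death).
    X : array-like, n x p
        Candidate covariates, without an intercept column.
    names : sequence of str, optional
    standardize : bool
        Centre/scale continuous columns to unit variance before analysis;
        binary (0/1) columns are never transformed.  Default True.
    include_intercept : bool
        Keep an intercept in every model, excluded from selection and
        always carrying the Zellner-form prior.  Default True.
    """

    def __init__(self, times, status, X, names=None, standardize=True,
                 include_intercept=True):
        times = np.asarray(times, float).ravel()
        if np.any(times <= 0):
            raise ValueError("times must be strictly positive (log undefined at 0)")
        X = np.atleast_2d(np.asarray(X, float))
        self.data = SelectionData(np.log(times), status, X,
                                  list(names) if names else ())
        self.include_intercept = bool(include_intercept)
        self.standardize = bool(standardize)
        self._build_design()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str, status_col: str,
                       covariates: Sequence[str], **kwargs) -> "AFTVariableSelection":
        return cls(
            df[time_col].to_numpy(float),
            df[status_col].to_numpy(),
            df[list(covariates)].to_numpy(float),
            names=list(covariates),
            **kwargs,
        )

    @classmethod
    def from_survival(cls, data: SurvivalDataset, **kwargs) -> "AFTVariableSelection":
        return cls(data.times, data.status, data.Z, names=list(data.names), **kwargs)

    @classmethod
    def from_selection_data(cls, data: SelectionData, **kwargs) -> "AFTVariableSelection":
        return cls(np.exp(data.y), data.status, data.X, names=list(data.names),
                   **kwargs)

    def _build_design(self):
        X = self.data.X.copy()
        self._binary = np.array(
            [set(np.unique(col)) <= {0.0, 1.0} for col in X.T], bool
        )
        if self.standardize:
            for j in range(X.shape[1]):
                if not self._binary[j]:
                    mu, sd = X[:, j].mean(), X[:, j].std(ddof=0)
                    if sd == 0:
                        raise ValueError(f"constant continuous column {j}")
                    X[:, j] = (X[:, j] - mu) / sd
        if self.include_intercept:
            self._W = np.column_stack([np.ones(X.shape[0]), X])
            self._offset = 1
        else:
            self._W = X
            self._offset = 0
        self._col_ss = np.einsum("ij,ij->j", self._W, self._W)

    # -- single-model marginal -------------------------------------------
    def _model_cols(self, gamma: Tuple[int, ...]) -> np.ndarray:
        base = list(range(self._offset))
        return np.array(base + [j + self._offset for j, g in enumerate(gamma) if g],
                        int)

    def log_marginal(self, gamma, prior: SelectionPrior) -> float:
        cols = self._model_cols(tuple(gamma))
        W = self._W[:, cols]
        mom_mask = np.ones(cols.size, bool)
        mom_mask[: self._offset] = False  # intercept: Zellner form always
        return laplace_log_marginal(
            self.data.y, self.data.status, W, prior,
            col_ss=self._col_ss[cols], mom_mask=mom_mask,
            model_label=f"gamma={tuple(gamma)}",
        )

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        prior: Optional[SelectionPrior] = None,
        coefficient_prior: str = "mom",
        elicitation: str = "unit_information",
        method: str = "auto",
        max_exhaustive: int = 15,
        gibbs_sweeps: int = 400,
        gibbs_burn: int = 50,
        seed: int = 0,
        **prior_kwargs,
    ) -> SelectionResults:
        """Compute posterior model probabilities and PIPs.

        ``method='auto'`` enumerates all 2^p models when p <= max_exhaustive
        and otherwise runs a Gibbs scan over inclusion indicators with
        Rao-Blackwellised PIPs.
        """
        if prior is None:
            prior = SelectionPrior(coefficient_prior=coefficient_prior,
                                   elicitation=elicitation, **prior_kwargs)
        p = self.data.p
        if method == "auto":
            method = "exhaustive" if p <= max_exhaustive else "gibbs"
        if method == "exhaustive":
            return self._fit_exhaustive(prior)
        return self._fit_gibbs(prior, gibbs_sweeps, gibbs_burn, seed)

    def _rank_ok(self, cols: np.ndarray) -> bool:
        if self._full_rank_ok:
            return True
        Wo = self._W[self.data.status == 1][:, cols]
        return np.linalg.matrix_rank(Wo) == cols.size

    def _prepare_rank(self):
        Wo = self._W[self.data.status == 1]
        self._full_rank_ok = (
            Wo.shape[0] >= Wo.shape[1]
            and np.linalg.matrix_rank(Wo) == Wo.shape[1]
        )

    def _eval_model(self, gamma, prior, cache):
        gamma = tuple(gamma)
        if gamma in cache:
            return cache[gamma]
        cols = self._model_cols(gamma)
        if not self._rank_ok(cols):
            warnings.warn(f"rank-deficient submodel {gamma}; assigned probability 0")
            cache[gamma] = -np.inf
            return -np.inf
        try:
            lm = self.log_marginal(gamma, prior)
        except LaplaceError as err:
            warnings.warn(str(err))
            lm = -np.inf
        cache[gamma] = lm
        return lm

    def _fit_exhaustive(self, prior: SelectionPrior) -> SelectionResults:
        p = self.data.p
        self._prepare_rank()
        cache: Dict[Tuple[int, ...], float] = {}
        gammas = list(itertools.product((0, 1), repeat=p))
        logpost = np.array([
            self._eval_model(g, prior, cache)
            + log_model_prior(sum(g), p, prior.a1, prior.b1)
            for g in gammas
        ])
        logZ = special.logsumexp(logpost)
        probs = np.exp(logpost - logZ)
        model_post = {g: float(pr) for g, pr in zip(gammas, probs)}
        pips = np.zeros(p)
        for g, pr in zip(gammas, probs):
            pips += pr * np.asarray(g)
        pips = np.clip(pips, 0.0, 1.0)  # guard float round-off at the ends
        return SelectionResults(
            names=list(self.data.names),
            model_posteriors=model_post,
            pips=pd.Series(pips, index=list(self.data.names)),
            prior=prior,
            exhaustive=True,
            log_marginals=cache,
        )

    def _fit_gibbs(self, prior: SelectionPrior, sweeps: int, burn: int,
                   seed: int) -> SelectionResults:
        p = self.data.p
        self._prepare_rank()
        rng = np.random.default_rng(seed)
        cache: Dict[Tuple[int, ...], float] = {}

        def logpost(g):
            lm = self._eval_model(g, prior, cache)
            return lm + log_model_prior(sum(g), p, prior.a1, prior.b1)

        gamma = [0] * p
        pip_acc = np.zeros(p)
        n_acc = 0
        for sweep in range(sweeps):
            order = rng.permutation(p)
            for j in order:
                g0 = list(gamma)
                g1 = list(gamma)
                g0[j], g1[j] = 0, 1
                lp0, lp1 = logpost(tuple(g0)), logpost(tuple(g1))
                p1 = special.expit(lp1 - lp0)
                gamma[j] = int(rng.random() < p1)
                if sweep >= burn:
                    pip_acc[j] += p1
            if sweep >= burn:
                n_acc += 1
        pips = pip_acc / max(n_acc, 1)
        # renormalise over the set of visited models
        visited = {g: lm for g, lm in cache.items() if np.isfinite(lm)}
        lps = np.array([
            lm + log_model_prior(sum(g), p, prior.a1, prior.b1)
            for g, lm in visited.items()
        ])
        probs = np.exp(lps - special.logsumexp(lps))
        model_post = {g: float(pr) for g, pr in zip(visited, probs)}
        return SelectionResults(
            names=list(self.data.names),
            model_posteriors=model_post,
            pips=pd.Series(pips, index=list(self.data.names)),
            prior=prior,
            exhaustive=False,
            log_marginals=cache,
        )
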