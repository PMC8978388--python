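"""Parametric baseline hazard families for hazard-based survival regression.

Implements the hazard h0, cumulative hazard H0, survival S0 = exp(-H0) and
the inverse cumulative hazard for a small set of parametric lifetime
distributions whose hazards cover the shapes seen in cancer-registry
follow-up (increasing, decreasing, unimodal, bathtub):

* ``PGW`` — Power Generalised Weibull with scale eta and shapes nu, delta:
  H0(t) = [1 + (t/eta)^nu]^(1/delta) - 1.  Reduces to the exponential
  distribution with rate 1/eta when nu = delta = 1 and to the Weibull when
  delta = 1.
* ``LOGLOGISTIC`` — S0(t) = 1 / (1 + (t/eta)^nu).
* ``LOGNORMAL`` — via the normal ccdf of log t, parameters (mu, sigma).
* ``GENGAMMA`` — Stacy generalised gamma, parameters (eta, a, c) mapped to
  ``scipy.stats.gengamma(a, c, scale=eta)``.
* ``GAMMA`` — shape nu, scale eta.

All functions are vectorised over time and evaluated in log space where
overflow is a risk (large t with extreme shapes).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "BaselineFamily",
    "BaselineParams",
    "baseline_hazard",
    "baseline_loghazard",
    "baseline_cumhaz",
    "baseline_survival",
    "baseline_cumhaz_inverse",
]


class BaselineFamily(str, Enum):
    PGW = "PGW"
    LOGLOGISTIC = "LOGLOGISTIC"
    LOGNORMAL = "LOGNORMAL"
    GENGAMMA = "GENGAMMA"
    GAMMA = "GAMMA"


_ARITY = {
    BaselineFamily.PGW: 3,
    BaselineFamily.LOGLOGISTIC: 2,
    BaselineFamily.LOGNORMAL: 2,
    BaselineFamily.GENGAMMA: 3,
    BaselineFamily.GAMMA: 2,
}


@dataclass(frozen=True)
class BaselineParams:
    """A baseline family together with its parameter vector xi.

    Parameter order: PGW (eta, nu, delta); LOGLOGISTIC (eta, nu);
    LOGNORMAL (mu, sigma); GENGAMMA (eta, a, c); GAMMA (eta, nu).
    All scale/shape parameters must be strictly positive (LOGNORMAL's
    location mu may be any real).
    """

    family: BaselineFamily
    params: tuple

    def __post_init__(self):
        family = BaselineFamily(self.family)
        object.__setattr__(self, "family", family)
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != _ARITY[family]:
            raise ValueError(
                f"{family.value} takes {_ARITY[family]} parameters, got {len(params)}"
            )
        positive = params if family is not BaselineFamily.LOGNORMAL else params[1:]
        if not all(np.isfinite(params)):
            raise ValueError(f"non-finite baseline parameters: {params}")
        if any(p <= 0 for p in positive):
            raise ValueError(
                f"scale/shape parameters must be strictly positive, got {params}"
            )


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def baseline_loghazard(t, p: BaselineParams):
    """log h0(t).  At t=0 the limit is -inf (nu>1), finite (nu=1) or +inf (nu<1)."""
    t = _check_t(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.log(t)
        if p.family is BaselineFamily.PGW:
            eta, nu, delta = p.params
            # log[1 + (t/eta)^nu] without overflow
            log1pu = np.logaddexp(0.0, nu * (logt - np.log(eta)))
            out = (
                np.log(nu)
                - np.log(delta)
                - nu * np.log(eta)
                + (nu - 1.0) * logt
                + (1.0 / delta - 1.0) * log1pu
            )
        elif p.family is BaselineFamily.LOGLOGISTIC:
            eta, nu = p.params
            log1pu = np.logaddexp(0.0, nu * (logt - np.log(eta)))
            out = np.log(nu) - nu * np.log(eta) + (nu - 1.0) * logt - log1pu
        elif p.family is BaselineFamily.LOGNORMAL:
            mu, sigma = p.params
            z = (logt - mu) / sigma
            out = stats.norm.logpdf(z) - np.log(sigma) - logt - stats.norm.logsf(z)
        elif p.family is BaselineFamily.GENGAMMA:
            eta, a, c = p.params
            d = stats.gengamma(a, c, scale=eta)
            out = d.logpdf(t) - d.logsf(t)
        elif p.family is BaselineFamily.GAMMA:
            eta, nu = p.params
            d = stats.gamma(nu, scale=eta)
            out = d.logpdf(t) - d.logsf(t)
        else:  # pragma: no cover
            raise ValueError(p.family)
    # t = 0 limits forced by the t^(nu-1) factor
    out = np.where(t == 0.0, _loghazard_at_zero(p), out)
    return out if out.ndim else float(out)


def _loghazard_at_zero(p: BaselineParams) -> float:
    if p.family is BaselineFamily.LOGNORMAL:
        return -np.inf
    if p.family is BaselineFamily.PGW:
        eta, nu, delta = p.params
        if nu > 1:
            return -np.inf
        if nu == 1:
            return -np.log(delta) - np.log(eta)
        return np.inf
    if p.family is BaselineFamily.LOGLOGISTIC:
        eta, nu = p.params
        if nu > 1:
            return -np.inf
        if nu == 1:
            return -np.log(eta)
        return np.inf
    if p.family is BaselineFamily.GAMMA:
        eta, nu = p.params
        if nu > 1:
            return -np.inf
        if nu == 1:
            return -np.log(eta)
        return np.inf
    # GENGAMMA: exponent of t is a*c - 1
    eta, a, c = p.params
    k = a * c
    if k > 1:
        return -np.inf
    if k == 1:
        return float(stats.gengamma(a, c, scale=eta).logpdf(0.0 + 1e-300))
    return np.inf


def baseline_hazard(t, p: BaselineParams):
    """Baseline hazard rate h0(t | xi)."""
    return np.exp(baseline_loghazard(t, p))


def baseline_cumhaz(t, p: BaselineParams):
    """Cumulative baseline hazard H0(t | xi); H0(0) = 0, non-decreasing."""
    t = _check_t(t)
    with np.errstate(divide="ignore"):
        logt = np.log(t)
        if p.family is BaselineFamily.PGW:
            eta, nu, delta = p.params
            log1pu = np.logaddexp(0.0, nu * (logt - np.log(eta)))
            out = np.expm1(log1pu / delta)
        elif p.family is BaselineFamily.LOGLOGISTIC:
            eta, nu = p.params
            out = np.logaddexp(0.0, nu * (logt - np.log(eta)))
        elif p.family is BaselineFamily.LOGNORMAL:
            mu, sigma = p.params
            out = -stats.norm.logsf((logt - mu) / sigma)
        elif p.family is BaselineFamily.GENGAMMA:
            eta, a, c = p.params
            out = -stats.gengamma(a, c, scale=eta).logsf(t)
        elif p.family is BaselineFamily.GAMMA:
            eta, nu = p.params
            out = -stats.gamma(nu, scale=eta).logsf(t)
        else:  # pragma: no cover
            raise ValueError(p.family)
    out = np.where(t == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def baseline_survival(t, p: BaselineParams):
    """S0(t) = exp(-H0(t))."""
    return np.exp(-baseline_cumhaz(t, p))


def baseline_cumhaz_inverse(u, p: BaselineParams):
    """Inverse cumulative hazard: t such that H0(t) = u.

    Closed form for PGW and log-logistic; for log-normal, gamma and
    generalised gamma through the inverse survival function (H0 = -log S0,
    so t = isf(exp(-u))).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("cumulative hazard must be nonnegative")
    if p.family is BaselineFamily.PGW:
        eta, nu, delta = p.params
        # eta * [(1+u)^delta - 1]^(1/nu), stable via log1p
        with np.errstate(divide="ignore"):
            inner = np.expm1(delta * np.log1p(u))
            out = eta * np.exp(np.log(inner, where=inner > 0, out=np.full_like(inner, -np.inf)) / nu)
        out = np.where(u == 0.0, 0.0, out)
    elif p.family is BaselineFamily.LOGLOGISTIC:
        eta, nu = p.params
        with np.errstate(divide="ignore"):
            inner = np.expm1(u)
            out = eta * np.exp(np.log(inner, where=inner > 0, out=np.full_like(inner, -np.inf)) / nu)
        out = np.where(u == 0.0, 0.0, out)
    elif p.family is BaselineFamily.LOGNORMAL:
        mu, sigma = p.params
        out = np.exp(mu + sigma * stats.norm.isf(np.exp(-u)))
        out = np.where(u == 0.0, 0.0, out)
    elif p.family is BaselineFamily.GENGAMMA:
        eta, a, c = p.params
        out = stats.gengamma(a, c, scale=eta).isf(np.exp(-u))
        out = np.where(u == 0.0, 0.0, out)
    elif p.family is BaselineFamily.GAMMA:
        eta, nu = p.params
        out = stats.gamma(nu, scale=eta).isf(np.exp(-u))
        out = np.where(u == 0.0, 0.0, out)
    else:  # pragma: no cover
        raise ValueError(p.family)
    return out if out.ndim else float(out)
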