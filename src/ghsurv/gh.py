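"""General hazards (GH) regression structure.

The GH model places covariates at two levels of a parametric baseline
hazard h0(. | xi):

    h(t | z) = h0(t * exp(z_tilde' theta_tilde) | xi) * exp(z' theta)

where ``theta_tilde`` are time-level coefficients acting inside the
baseline (time-dependent effects) and ``theta`` are hazard-level
coefficients.  Special cases: proportional hazards (PH, theta_tilde = 0),
accelerated hazards (AH, theta = 0) and accelerated failure time
(AFT, theta_tilde = theta with identical covariate sets).

The cumulative hazard has the closed form

    H(t | z) = exp(z' theta - z_tilde' theta_tilde) * H0(t * exp(z_tilde' theta_tilde))

obtained by the change of variables s -> s * exp(z_tilde' theta_tilde)
in the integral of the hazard, so no numerical integration is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .baselines import (
    BaselineParams,
    baseline_cumhaz,
    baseline_loghazard,
)

__all__ = [
    "GHStructure",
    "GHParameters",
    "SurvivalDataset",
    "gh_hazard",
    "gh_cumhaz",
    "gh_logsurvival",
    "gh_loglik",
    "hazard_ratios",
]


class GHStructure(str, Enum):
    GH = "GH"
    PH = "PH"
    AFT = "AFT"
    AH = "AH"


@dataclass(frozen=True)
class GHParameters:
    """Baseline parameters xi plus the two coefficient blocks.

    ``theta_tilde`` multiplies time-level covariates z_tilde, ``theta``
    hazard-level covariates z.  Structure constraints (PH: theta_tilde=0;
    AH: theta=0; AFT: theta_tilde=theta) are the caller's contract and can
    be asserted with :meth:`check_structure`.
    """

    baseline: BaselineParams
    theta_tilde: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        object.__setattr__(self, "theta_tilde", np.atleast_1d(np.asarray(self.theta_tilde, float)))
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))

    def check_structure(self, structure: GHStructure) -> None:
        structure = GHStructure(structure)
        if structure is GHStructure.PH and np.any(self.theta_tilde != 0):
            raise ValueError("PH requires theta_tilde = 0")
        if structure is GHStructure.AH and np.any(self.theta != 0):
            raise ValueError("AH requires theta = 0")
        if structure is GHStructure.AFT and not np.array_equal(self.theta_tilde, self.theta):
            raise ValueError("AFT requires theta_tilde = theta")


@dataclass
class SurvivalDataset:
    """Right-censored survival data with two covariate design matrices.

    times
        observed follow-up (min of event and censoring time), strictly
        positive, in years.
    status
        1 = event (death), 0 = right-censored.
    Z
        n x q hazard-level design matrix.
    Z_tilde
        n x q_tilde time-level design matrix; typically a column subset of
        Z (by default, its continuous columns — binary comorbidities are
        not given time-dependent effects).
    """

    times: np.ndarray
    status: np.ndarray
    Z: np.ndarray
    Z_tilde: np.ndarray
    names: Sequence[str] = ()
    tilde_names: Sequence[str] = ()

    def __post_init__(self):
        self.times = np.asarray(self.times, float).ravel()
        self.status = np.asarray(self.status).astype(int).ravel()
        self.Z = np.atleast_2d(np.asarray(self.Z, float))
        self.Z_tilde = np.atleast_2d(np.asarray(self.Z_tilde, float))
        n = self.times.size
        if self.Z.shape[0] != n and self.Z.size == 0:
            self.Z = np.zeros((n, 0))
        if self.Z_tilde.shape[0] != n and self.Z_tilde.size == 0:
            self.Z_tilde = np.zeros((n, 0))
        if self.status.size != n or self.Z.shape[0] != n or self.Z_tilde.shape[0] != n:
            raise ValueError("inconsistent number of rows across fields")
        if np.any(self.times <= 0):
            raise ValueError("times must be strictly positive")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0/1")
        if not self.names:
            self.names = [f"z{j}" for j in range(self.Z.shape[1])]
        if not self.tilde_names:
            self.tilde_names = [f"zt{j}" for j in range(self.Z_tilde.shape[1])]

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str,
        status_col: str,
        covariates: Sequence[str],
        tilde_covariates: Optional[Sequence[str]] = None,
    ) -> "SurvivalDataset":
        """Build from a tidy table.

        If ``tilde_covariates`` is None, the time level receives the
        continuous covariates only (columns with values outside {0, 1}).
        """
        Z = df[list(covariates)].to_numpy(float)
        if tilde_covariates is None:
            tilde_covariates = [
                c for c in covariates if not set(np.unique(df[c])) <= {0.0, 1.0}
            ]
        Zt = df[list(tilde_covariates)].to_numpy(float)
        if Zt.size == 0:
            Zt = np.zeros((len(df), 0))
        return cls(
            times=df[time_col].to_numpy(float),
            status=df[status_col].to_numpy(),
            Z=Z,
            Z_tilde=Zt,
            names=list(covariates),
            tilde_names=list(tilde_covariates),
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.times, "status": self.status})
        for j, name in enumerate(self.names):
            out[name] = self.Z[:, j]
        return out


def _lincomb(x, coef):
    x = np.asarray(x, float)
    coef = np.asarray(coef, float)
    if coef.size == 0:
        return np.zeros(x.shape[:-1]) if x.ndim > 1 else 0.0
    if x.ndim == 1 and x.size != coef.size:
        raise ValueError(f"covariate length {x.size} != coefficient length {coef.size}")
    if x.ndim > 1 and x.shape[-1] != coef.size:
        raise ValueError(f"covariate width {x.shape[-1]} != coefficient length {coef.size}")
    return x @ coef


def gh_hazard(t, z, z_tilde, par: GHParameters):
    """h(t | z) = h0(t e^{a}) e^{b} with a = z_tilde' theta_tilde, b = z' theta."""
    a = _lincomb(z_tilde, par.theta_tilde)
    b = _lincomb(z, par.theta)
    t = np.asarray(t, float)
    return np.exp(baseline_loghazard(t * np.exp(a), par.baseline) + b)


def gh_cumhaz(t, z, z_tilde, par: GHParameters):
    """Closed-form cumulative hazard e^{b-a} H0(t e^{a})."""
    a = _lincomb(z_tilde, par.theta_tilde)
    b = _lincomb(z, par.theta)
    t = np.asarray(t, float)
    return np.exp(b - a) * baseline_cumhaz(t * np.exp(a), par.baseline)


def gh_logsurvival(t, z, z_tilde, par: GHParameters):
    return -gh_cumhaz(t, z, z_tilde, par)


def gh_loglik(data: SurvivalDataset, par: GHParameters) -> float:
    """Right-censored log-likelihood of the GH model.

    sum_i [ status_i * log h(t_i | z_i) - H(t_i | z_i) ].  Returns -inf for
    non-finite parameter values so samplers can reject safely.
    """
    theta_all = np.concatenate([par.theta_tilde, par.theta, par.baseline.params])
    if not np.all(np.isfinite(theta_all)):
        return -np.inf
    a = _lincomb(data.Z_tilde, par.theta_tilde)
    b = _lincomb(data.Z, par.theta)
    ts = data.times * np.exp(a)
    logh = baseline_loghazard(ts, par.baseline) + b
    cumh = np.exp(b - a) * baseline_cumhaz(ts, par.baseline)
    ll = np.sum(np.where(data.status == 1, logh, 0.0)) - np.sum(cumh)
    return float(ll) if np.isfinite(ll) else -np.inf


def hazard_ratios(par: GHParameters) -> np.ndarray:
    """Hazard ratios exp(theta) of the hazard-level coefficients."""
    return np.exp(par.theta)
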