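"""Delayed-treatment-effect survival model: hazard, survival, likelihood and RMST.

The outcome model is a piecewise-exponential model with a delayed treatment
effect: both arms share the hazard ``lambda * exp(u * beta_u)`` until a known
change point ``t0``, after which the intervention arm's hazard is multiplied by
``exp(beta_z)``. The binary confounder ``u`` acts additively on the log hazard.
Two codings of ``u`` are supported: {0, 1} (simulation convention, propensity
with intercept) and {-1, +1} (empirical convention, intercept-free propensity).

Everything here is closed form; these functions are the ground truth against
which the sampler, the weighted estimators and the simulation study are judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Coding",
    "SubjectRecord",
    "Cohort",
    "OutcomeParams",
    "PropensityParams",
    "SensitivityPair",
    "hazard",
    "survival",
    "log_likelihood",
    "rmst_true",
    "adjusted_drmst_true",
    "treatment_prob",
]


class Coding(Enum):
    """Coding convention for the binary confounder ``u``."""

    ZERO_ONE = "zero_one"
    MINUS_PLUS_ONE = "minus_plus_one"

    @property
    def levels(self) -> tuple[float, float]:
        """(low, high) coded values."""
        return (0.0, 1.0) if self is Coding.ZERO_ONE else (-1.0, 1.0)


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class OutcomeParams:
    """Parameters of the delayed-effect outcome model.

    Attributes
    ----------
    log_lambda : float
        Log baseline hazard (events per month) for a subject with ``u`` at the
        zero of its coded scale.
    beta_z : float
        Log hazard ratio of treatment after the change point; before ``t0``
        treatment has no effect.
    beta_u : float
        Log-hazard coefficient of the coded confounder value.
    t0 : float
        Change point of the treatment effect, in months; the indicator is
        strict, so ``t == t0`` falls in the pre-effect segment.
    """

    log_lambda: float
    beta_z: float
    beta_u: float
    t0: float

    def __post_init__(self) -> None:
        _require_finite(
            log_lambda=self.log_lambda, beta_z=self.beta_z, beta_u=self.beta_u, t0=self.t0
        )
        if self.t0 <= 0:
            raise ValueError(f"t0 must be positive, got {self.t0}")

    @property
    def lam(self) -> float:
        return math.exp(self.log_lambda)


@dataclass(frozen=True)
class PropensityParams:
    """Logistic treatment-assignment model Pr(z=1|u) = expit(alpha0 + alpha1*u).

    Under the {-1,+1} coding the intercept is absorbed into the coding and must
    be exactly zero; the empirical-mode convention Pr(z=1|u) = expit(-alpha_u*u)
    corresponds to ``alpha1 = -alpha_u``.
    """

    alpha0: float
    alpha1: float
    alpha_x: Optional[tuple[float, ...]] = None
    coding: Coding = Coding.ZERO_ONE

    def __post_init__(self) -> None:
        _require_finite(alpha0=self.alpha0, alpha1=self.alpha1)
        if self.coding is Coding.MINUS_PLUS_ONE and self.alpha0 != 0.0:
            raise ValueError("alpha0 must be 0 under the -1/+1 coding")


@dataclass(frozen=True)
class SensitivityPair:
    """One user-specified (alpha_u, beta_u) sensitivity grid point.

    ``alpha_u`` is the confounder-exposure association: under {0,1} coding it is
    the slope alpha1 of the intercept-full logistic model (the intercept is
    supplied separately via ``alpha0``); under {-1,+1} coding the propensity is
    the intercept-free expit(-alpha_u * u). ``beta_u`` is the confounder's
    log-hazard coefficient. ``prevalence_prior`` is the Beta(a, b) prior on the
    prevalence of the high confounder level.
    """

    alpha_u: float
    beta_u: float
    coding: Coding = Coding.MINUS_PLUS_ONE
    prevalence_prior: tuple[float, float] = (1.0, 1.0)
    alpha0: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.prevalence_prior
        if a <= 0 or b <= 0:
            raise ValueError("prevalence prior Beta(a, b) requires a > 0, b > 0")
        _require_finite(alpha_u=self.alpha_u, beta_u=self.beta_u, alpha0=self.alpha0)

    def propensity(self) -> PropensityParams:
        """The implied fixed propensity model on the coded scale."""
        if self.coding is Coding.MINUS_PLUS_ONE:
            return PropensityParams(0.0, -self.alpha_u, coding=self.coding)
        return PropensityParams(self.alpha0, self.alpha_u, coding=self.coding)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: follow-up time (months), event and arm indicators,
    optional measured covariates and, when simulated, the true confounder."""

    time: float
    event: int
    arm: int
    covariates: Optional[tuple[float, ...]] = None
    u_true: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be nonnegative, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        if self.arm not in (0, 1):
            raise ValueError(f"arm must be 0 or 1, got {self.arm}")


@dataclass
class Cohort:
    """A study cohort stored as parallel arrays.

    Arrays are the native representation (the sampler and the weighted
    estimators are vectorized); ``records`` materialises ``SubjectRecord``
    views for scalar APIs.
    """

    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray
    coding: Coding = Coding.ZERO_ONE
    u_true: Optional[np.ndarray] = None
    covariates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.arm = np.asarray(self.arm, dtype=int)
        n = self.time.shape[0]
        if n == 0:
            raise ValueError("cohort must be nonempty")
        for name, arr in (("event", self.event), ("arm", self.arm)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != time length {n}")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must be binary 0/1")
        if (self.time < 0).any():
            raise ValueError("times must be nonnegative")
        if self.u_true is not None:
            self.u_true = np.asarray(self.u_true, dtype=float)
            lo, hi = self.coding.levels
            if not np.isin(self.u_true, (lo, hi)).all():
                raise ValueError(
                    f"u_true values must lie in the active coding set {{{lo}, {hi}}}"
                )

    @property
    def n(self) -> int:
        return int(self.time.shape[0])

    @property
    def records(self) -> list[SubjectRecord]:
        out = []
        for i in range(self.n):
            out.append(
                SubjectRecord(
                    time=float(self.time[i]),
                    event=int(self.event[i]),
                    arm=int(self.arm[i]),
                    u_true=None if self.u_true is None else float(self.u_true[i]),
                )
            )
        return out

    def require_both_arms(self) -> None:
        if not (self.arm == 1).any() or not (self.arm == 0).any():
            raise ValueError("comparative analysis requires both arms to be present")

    @classmethod
    def from_records(
        cls, records: Sequence[SubjectRecord], coding: Coding = Coding.ZERO_ONE
    ) -> "Cohort":
        u = None
        if records and all(r.u_true is not None for r in records):
            u = np.array([r.u_true for r in records], dtype=float)
        return cls(
            time=np.array([r.time for r in records], dtype=float),
            event=np.array([r.event for r in records], dtype=int),
            arm=np.array([r.arm for r in records], dtype=int),
            coding=coding,
            u_true=u,
        )

    def to_frame(self, include_u: bool = True) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event, "arm": self.arm})
        if include_u and self.u_true is not None:
            df["u_true"] = self.u_true
        return df


# ---------------------------------------------------------------------------
# Closed-form model quantities
# ---------------------------------------------------------------------------


def hazard(t: float, z: int, u: float, params: OutcomeParams) -> float:
    """Hazard rate (per month) at time ``t`` for arm ``z`` and coded confounder ``u``.

    lambda * exp(u*beta_u + 1(t > t0) * z * beta_z), strict inequality at t0.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    post = 1.0 if t > params.t0 else 0.0
    return params.lam * math.exp(u * params.beta_u + post * z * params.beta_z)


def _cum_hazard(t: float, z: int, u: float, params: OutcomeParams) -> float:
    r = params.lam * math.exp(u * params.beta_u)
    if z == 0 or t <= params.t0:
        return r * t
    return r * params.t0 + r * math.exp(params.beta_z) * (t - params.t0)


def survival(t: float, z: int, u: float, params: OutcomeParams) -> float:
    """Survival probability S(t | z, u); continuous at the change point."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return math.exp(-_cum_hazard(t, z, u, params))


def log_likelihood(record: SubjectRecord, u: float, params: OutcomeParams) -> float:
    """Log likelihood contribution of one subject given the coded confounder value.

    event * log h(t) - H(t); reduces to the exponential log likelihood when the
    subject is in the control arm or was observed before the change point.
    """
    ll = -_cum_hazard(record.time, record.arm, u, params)
    if record.event:
        ll += math.log(hazard(record.time, record.arm, u, params))
    return ll


def rmst_true(z: int, u: float, params: OutcomeParams, tau: float) -> float:
    """Restricted mean survival time on [0, tau] in closed form (months).

    The survival function is exponential on [0, min(tau, t0)] and, for the
    treated arm beyond t0, exponential with rate r*exp(beta_z); the integral is
    the sum of at most two segment integrals.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    r = params.lam * math.exp(u * params.beta_u)
    if z == 0 or tau <= params.t0 or params.beta_z == 0.0:
        if r == 0.0:
            return tau
        return -math.expm1(-r * tau) / r
    r2 = r * math.exp(params.beta_z)
    if r == 0.0:
        return tau
    head = -math.expm1(-r * params.t0) / r
    s0 = math.exp(-r * params.t0)
    if r2 == 0.0:
        return head + s0 * (tau - params.t0)
    return head + s0 * (-math.expm1(-r2 * (tau - params.t0)) / r2)


def adjusted_drmst_true(
    outcome: OutcomeParams,
    prevalence: float,
    tau: float,
    coding: Coding = Coding.ZERO_ONE,
) -> float:
    """True confounder-adjusted dRMST: E_u[RMST(z=1, u) - RMST(z=0, u)].

    ``u`` is Bernoulli(prevalence) on the high level of the active coding. This
    is the estimand every adjustment method in the package targets.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    lo, hi = coding.levels
    out = 0.0
    for u, w in ((hi, prevalence), (lo, 1.0 - prevalence)):
        if w == 0.0:
            continue
        out += w * (rmst_true(1, u, outcome, tau) - rmst_true(0, u, outcome, tau))
    return out


def treatment_prob(u: np.ndarray | float, propensity: PropensityParams) -> np.ndarray | float:
    """Pr(z = 1 | u) under the logistic assignment model, on the coded scale."""
    from scipy.special import expit

    return expit(propensity.alpha0 + propensity.alpha1 * np.asarray(u, dtype=float))
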