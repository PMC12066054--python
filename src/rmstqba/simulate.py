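"""Simulation of confounded cohorts under the delayed-treatment-effect model.

Generates cohorts in which a binary confounder ``u`` shifts both the hazard
(through ``beta_u``) and treatment assignment (through a logistic model), with
administrative censoring at the study end ``T``. The four imbalance scenarios
used throughout the package (small/large, each in two directions) are provided
as named presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import (
    Coding,
    Cohort,
    OutcomeParams,
    PropensityParams,
    treatment_prob,
)

__all__ = [
    "ScenarioSpec",
    "IMBALANCE_PRESETS",
    "scenario",
    "draw_confounder",
    "assign_treatment",
    "draw_event_time",
    "apply_admin_censoring",
    "simulate_cohort",
]

# Default study conditions: N=300 subjects, baseline hazard 0.073/month,
# post-change-point treatment HR 0.68, change point 5 months, study end 48
# months, confounder prevalence 0.5.
DEFAULT_N = 300
DEFAULT_LAMBDA = 0.073
DEFAULT_BETA_Z = float(np.log(0.68))
DEFAULT_T0 = 5.0
DEFAULT_T_END = 48.0
DEFAULT_PREVALENCE = 0.5

# (alpha0, alpha1) presets and the treated probabilities they induce:
#   small 1: Pr(z|u=1)=0.6, Pr(z|u=0)=0.4     small 2: 0.4 / 0.6
#   large 1: Pr(z|u=1)=0.8, Pr(z|u=0)=0.2     large 2: 0.2 / 0.8
IMBALANCE_PRESETS: dict[str, tuple[float, float]] = {
    "small1": (float(np.log(2 / 3)), float(2 * np.log(3 / 2))),
    "small2": (float(np.log(3 / 2)), float(2 * np.log(2 / 3))),
    "large1": (float(np.log(1 / 4)), float(2 * np.log(4))),
    "large2": (float(np.log(4)), float(2 * np.log(1 / 4))),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one simulated study condition."""

    n: int
    outcome: OutcomeParams
    propensity: PropensityParams
    prevalence: float = DEFAULT_PREVALENCE
    admin_censor_T: float = DEFAULT_T_END
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("scenario needs n >= 2")
        if self.admin_censor_T <= self.outcome.t0:
            raise ValueError("administrative censoring time must exceed t0")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


def scenario(
    imbalance: str,
    beta_u: float,
    n: int = DEFAULT_N,
    seed: int = 0,
) -> ScenarioSpec:
    """Named preset scenario: one of small1/small2/large1/large2 plus beta_u."""
    try:
        alpha0, alpha1 = IMBALANCE_PRESETS[imbalance]
    except KeyError:
        raise ValueError(
            f"unknown imbalance {imbalance!r}; choose from {sorted(IMBALANCE_PRESETS)}"
        ) from None
    outcome = OutcomeParams(
        log_lambda=float(np.log(DEFAULT_LAMBDA)),
        beta_z=DEFAULT_BETA_Z,
        beta_u=beta_u,
        t0=DEFAULT_T0,
    )
    return ScenarioSpec(
        n=n,
        outcome=outcome,
        propensity=PropensityParams(alpha0, alpha1, coding=Coding.ZERO_ONE),
        seed=seed,
    )


def draw_confounder(
    n: int,
    prevalence: float,
    rng: np.random.Generator,
    coding: Coding = Coding.ZERO_ONE,
) -> np.ndarray:
    """i.i.d. Bernoulli(prevalence) draws mapped onto the active coding."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    high = rng.random(n) < prevalence
    lo, hi = coding.levels
    return np.where(high, hi, lo)


def assign_treatment(
    u: np.ndarray, propensity: PropensityParams, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli treatment assignment with Pr(z=1|u) = expit(alpha0 + alpha1*u)."""
    p = treatment_prob(u, propensity)
    return (rng.random(len(u)) < p).astype(int)


def draw_event_time(
    z: np.ndarray, u: np.ndarray, outcome: OutcomeParams, rng: np.random.Generator
) -> np.ndarray:
    """Exact inverse-CDF sampling from the piecewise-exponential event model.

    Draw E ~ Exp(1); with subject rate r = lambda*exp(u*beta_u) the event time
    is E/r until the cumulative hazard reaches r*t0, after which treated
    subjects accrue hazard at rate r*exp(beta_z).
    """
    z = np.asarray(z)
    u = np.asarray(u, dtype=float)
    e = rng.exponential(size=len(z))
    r = outcome.lam * np.exp(u * outcome.beta_u)
    t = e / r
    crossed = (z == 1) & (e > r * outcome.t0)
    r2 = r * np.exp(outcome.beta_z)
    t = np.where(crossed, outcome.t0 + (e - r * outcome.t0) / r2, t)
    return t


def apply_admin_censoring(t: np.ndarray, T: float) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring at study end T; ties at T count as events."""
    if T <= 0:
        raise ValueError("T must be positive")
    t = np.asarray(t, dtype=float)
    return np.minimum(t, T), (t <= T).astype(int)


def simulate_cohort(spec: ScenarioSpec, coding: Coding = Coding.ZERO_ONE) -> Cohort:
    """Simulate one cohort; reproducible given ``spec.seed``.

    Sub-streams for the confounder, treatment assignment and event times are
    spawned deterministically from the root seed so that each stage's draws are
    stable if later stages gain structure.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_u, rng_z, rng_t = (np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(3))
    u = draw_confounder(spec.n, spec.prevalence, rng_u, coding)
    z = assign_treatment(u, spec.propensity, rng_z)
    t_event = draw_event_time(z, u, spec.outcome, rng_t)
    time, event = apply_admin_censoring(t_event, spec.admin_censor_T)
    return Cohort(time=time, event=event, arm=z, coding=coding, u_true=u)
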