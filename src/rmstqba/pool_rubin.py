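"""Rubin's rules for pooling per-imputation dRMST estimates.

The pooled point estimate is the mean of the K per-imputation estimates; the
pooled variance adds the between-imputation variance, inflated by (1 + 1/K),
to the mean within-imputation variance. Confidence intervals use a Student's
t reference; the default degrees of freedom follow Barnard & Rubin's
small-sample adjustment with the complete-data df taken from the Kish
effective sample size of the IPT weights, with the classic Rubin df available
as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.stats import t as student_t

__all__ = ["PooledEstimate", "pool_point", "pool_variance", "pooled_ci", "pool"]


@dataclass(frozen=True)
class PooledEstimate:
    """Pooled dRMST with t-based confidence interval."""

    gamma_hat: float
    eta_hat: float
    ci_low: float
    ci_high: float
    df: float
    alpha_level: float
    significant: bool
    within: float
    between: float
    K: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.gamma_hat <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def pool_point(gammas: np.ndarray) -> float:
    """Pooled point estimate: the arithmetic mean of the K per-imputation
    estimates (Rubin's rule for the point estimate)."""
    gammas = np.asarray(gammas, dtype=float)
    if len(gammas) < 2:
        raise ValueError("pooling requires K >= 2 imputations")
    return float(gammas.mean())


def _between(gammas: np.ndarray) -> float:
    return float(np.var(gammas, ddof=1))


def pool_variance(gammas: np.ndarray, etas: np.ndarray) -> float:
    """Pooled variance: mean within-imputation variance plus (1 + 1/K) times
    the between-imputation variance of the point estimates."""
    gammas = np.asarray(gammas, dtype=float)
    etas = np.asarray(etas, dtype=float)
    if len(gammas) != len(etas):
        raise ValueError("gammas and etas must have equal length")
    if len(gammas) < 2:
        raise ValueError("pooling requires K >= 2 imputations")
    if np.any(etas < 0):
        raise ValueError("per-imputation variances must be nonnegative")
    K = len(gammas)
    return float(etas.mean() + (1.0 + 1.0 / K) * _between(gammas))


def _barnard_rubin_df(K: int, within: float, between: float, df_complete: float) -> float:
    """Barnard-Rubin (small-sample) adjusted degrees of freedom."""
    total = within + (1.0 + 1.0 / K) * between
    if between <= 0 or total <= 0:
        return float("inf")
    frac_missing = (1.0 + 1.0 / K) * between / total
    nu_old = (K - 1) / frac_missing**2
    nu_obs = (
        (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - frac_missing)
    )
    return float(1.0 / (1.0 / nu_old + 1.0 / nu_obs))


def _rubin_df(K: int, within: float, between: float) -> float:
    if between <= 0:
        return float("inf")
    r = (1.0 + 1.0 / K) * between / within if within > 0 else float("inf")
    return float((K - 1) * (1.0 + 1.0 / r) ** 2)


def pooled_ci(
    gammas: np.ndarray,
    etas: np.ndarray,
    alpha_level: float = 0.05,
    df_complete: Optional[float] = None,
    rule: Literal["barnard-rubin", "rubin"] = "barnard-rubin",
) -> PooledEstimate:
    """Pooled estimate with t-based CI and significance flag (CI excludes 0).

    ``df_complete`` is the complete-data degrees of freedom used by the
    Barnard-Rubin adjustment; callers supply it from the weighted analysis's
    effective sample size (defaults to K-derived large-sample behaviour when
    omitted).
    """
    gammas = np.asarray(gammas, dtype=float)
    etas = np.asarray(etas, dtype=float)
    gamma_hat = pool_point(gammas)
    eta_hat = pool_variance(gammas, etas)
    K = len(gammas)
    within = float(etas.mean())
    between = _between(gammas)
    if rule == "rubin" or df_complete is None:
        df = _rubin_df(K, within, between)
    else:
        df = _barnard_rubin_df(K, within, between, df_complete)
    if eta_hat <= 0:
        ci_low = ci_high = gamma_hat
    else:
        tcrit = (
            student_t.ppf(1.0 - alpha_level / 2.0, df)
            if np.isfinite(df)
            else float(student_t.ppf(1.0 - alpha_level / 2.0, 1e12))
        )
        half = tcrit * float(np.sqrt(eta_hat))
        ci_low, ci_high = gamma_hat - half, gamma_hat + half
    return PooledEstimate(
        gamma_hat=gamma_hat,
        eta_hat=eta_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        df=df,
        alpha_level=alpha_level,
        significant=not (ci_low <= 0.0 <= ci_high),
        within=within,
        between=between,
        K=K,
    )


def kish_df_complete(weights: np.ndarray, arm: np.ndarray) -> float:
    """Complete-data df from the Kish effective sample size of the weights,
    summed over arms, minus one mean per arm."""
    weights = np.asarray(weights, dtype=float)
    arm = np.asarray(arm)
    ess = 0.0
    for a in (0, 1):
        w = weights[arm == a]
        ess += float(w.sum() ** 2 / np.sum(w**2))
    return max(ess - 2.0, 1.0)


def pool(
    gammas: np.ndarray,
    etas: np.ndarray,
    alpha_level: float = 0.05,
    df_complete: Optional[float] = None,
    rule: Literal["barnard-rubin", "rubin"] = "barnard-rubin",
) -> PooledEstimate:
    """Convenience wrapper: point, variance and CI in one call."""
    return pooled_ci(gammas, etas, alpha_level, df_complete, rule)
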