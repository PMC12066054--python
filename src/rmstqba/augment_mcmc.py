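"""Bayesian data augmentation of an unmeasured binary confounder.

Draws from the joint posterior over (log lambda, beta_z, phi, u_1..u_N) given
user-specified confounder-exposure and confounder-outcome associations
(alpha_u, beta_u). The sampler is a Metropolis-within-Gibbs scheme:

* u_i | rest   — exact two-point Bernoulli conditional, updated for all
  subjects simultaneously (each conditional depends only on the shared
  parameters and subject i's own record, so the block update is valid Gibbs);
* phi | u      — conjugate Beta update of the confounder prevalence;
* log lambda, beta_z | rest — Gaussian random-walk Metropolis, with proposal
  scales adapted during burn-in (target acceptance ~0.44) and frozen after.

The retained post-burn-in draws of u are the multiple imputations consumed by
the weighted analysis; each is paired with its same-iteration parameter draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .model_core import Coding, Cohort, OutcomeParams, SensitivityPair, treatment_prob

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "SamplerState",
    "PosteriorDraws",
    "ImputationSet",
    "u_conditional_prob",
    "update_phi",
    "update_outcome_params",
    "run_sampler",
    "effective_sample_size",
    "extract_imputations",
]


@dataclass(frozen=True)
class PriorSpec:
    """Vague default priors: log(lambda), beta_z ~ N(mu0, sigma0_sq);
    prevalence phi ~ Beta(a_phi, b_phi)."""

    mu0: float = 0.0
    sigma0_sq: float = 100.0
    a_phi: float = 1.0
    b_phi: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be positive")
        if self.a_phi <= 0 or self.b_phi <= 0:
            raise ValueError("Beta prior requires a_phi > 0 and b_phi > 0")


@dataclass(frozen=True)
class McmcConfig:
    """Chain length and tuning. Defaults follow the 5,000-draw / 4,000 burn-in
    schedule used for the grid analyses; ``thin`` applies at extraction."""

    n_iter: int = 5000
    burn_in: int = 4000
    thin: int = 1
    seed: int = 0
    proposal_sd: tuple[float, float] = (0.1, 0.1)
    init: Optional[tuple[float, float, float]] = None  # (log lambda, beta_z, phi)
    adapt: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if min(self.proposal_sd) <= 0:
            raise ValueError("proposal standard deviations must be positive")


@dataclass
class SamplerState:
    """Current values of the sampled parameters."""

    log_lambda: float
    beta_z: float
    phi: float


@dataclass
class PosteriorDraws:
    """Full MCMC output: parameter chains, coded u draws, diagnostics."""

    log_lambda: np.ndarray
    beta_z: np.ndarray
    phi: np.ndarray
    u_draws: np.ndarray  # (n_iter, N) coded int8
    acceptance: dict[str, float]
    ess: dict[str, float]
    coding: Coding
    burn_in: int

    @property
    def n_iter(self) -> int:
        return int(self.log_lambda.shape[0])

    def ess_u_mean(self) -> float:
        """Average effective sample size of the post-burn-in u_i chains."""
        post = self.u_draws[self.burn_in :].astype(float)
        vals = []
        for j in range(post.shape[1]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals.append(effective_sample_size(post[:, j]))
        return float(np.mean(vals))


@dataclass
class ImputationSet:
    """K retained imputations of u, paired with same-iteration parameter draws."""

    u: np.ndarray  # (K, N) coded
    phi: np.ndarray
    log_lambda: np.ndarray
    beta_z: np.ndarray
    pair: SensitivityPair

    @property
    def K(self) -> int:
        return int(self.u.shape[0])


# ---------------------------------------------------------------------------
# Likelihood plumbing (vectorized over subjects)
# ---------------------------------------------------------------------------


class _LikelihoodWorkspace:
    """Precomputed per-subject quantities for the delayed-effect likelihood.

    The cumulative hazard decomposes as r*(A + exp(beta_z)*B) with
    r = exp(log_lambda + u*beta_u), A the exposure before the change point (or
    the whole follow-up for controls) and B the treated exposure after it.
    """

    def __init__(self, cohort: Cohort, pair: SensitivityPair):
        t, z, d = cohort.time, cohort.arm, cohort.event
        t0 = None
        self.t = t
        self.z = z
        self.d = d.astype(float)
        self.pair = pair
        self.beta_u = pair.beta_u
        self.lo, self.hi = cohort.coding.levels
        # these depend on t0 which lives in the outcome model; t0 is fixed and
        # user-supplied, carried on the workspace
        self.t0: float = np.nan
        self.A: np.ndarray = np.empty(0)
        self.B: np.ndarray = np.empty(0)
        self.post: np.ndarray = np.empty(0)
        # fixed propensity contributions z*log g + (1-z)*log(1-g) at each level
        prop = pair.propensity()
        self.log_g = {}
        for level in (self.lo, self.hi):
            p = float(treatment_prob(level, prop))
            with np.errstate(divide="ignore"):
                lg = z * np.log(p) + (1 - z) * np.log1p(-p)
            if not np.isfinite(lg).all():
                bad = int(np.argmin(np.isfinite(lg)))
                raise ValueError(
                    f"degenerate propensity: subject {bad} has probability 0 of its "
                    f"observed arm at confounder level {level}"
                )
            self.log_g[level] = lg

    def set_t0(self, t0: float) -> None:
        self.t0 = t0
        treated = self.z == 1
        self.A = np.where(treated, np.minimum(self.t, t0), self.t)
        self.B = np.where(treated, np.maximum(self.t - t0, 0.0), 0.0)
        self.post = ((self.t > t0) & treated).astype(float)

    def loglik_vector(self, log_lambda: float, beta_z: float, u: np.ndarray) -> np.ndarray:
        """Per-subject log likelihood at coded confounder vector u."""
        lin = log_lambda + u * self.beta_u
        cum = np.exp(lin) * (self.A + np.exp(beta_z) * self.B)
        return self.d * (lin + self.post * beta_z) - cum

    def loglik_total(self, log_lambda: float, beta_z: float, u: np.ndarray) -> float:
        return float(self.loglik_vector(log_lambda, beta_z, u).sum())

    def u_high_probs(self, log_lambda: float, beta_z: float, phi: float) -> np.ndarray:
        """Pr(u_i = high | rest) for every subject, computed on the log scale."""
        lw_hi = self.loglik_vector(log_lambda, beta_z, np.full_like(self.t, self.hi))
        lw_lo = self.loglik_vector(log_lambda, beta_z, np.full_like(self.t, self.lo))
        lw_hi = lw_hi + self.log_g[self.hi]
        lw_lo = lw_lo + self.log_g[self.lo]
        with np.errstate(divide="ignore"):
            logit = (lw_hi - lw_lo) + (np.log(phi) - np.log1p(-phi))
        return expit(logit)


def u_conditional_prob(
    i: int,
    state: SamplerState,
    pair: SensitivityPair,
    cohort: Cohort,
    outcome_t0: float,
) -> float:
    """Pr(u_i = high level | everything else) for a single subject.

    Equals A/(A+B) where A and B are the unnormalised joint-posterior factors
    (outcome likelihood x propensity likelihood x Bernoulli prior) at the high
    and low confounder levels; evaluated in log space.
    """
    ws = _LikelihoodWorkspace(cohort, pair)
    ws.set_t0(outcome_t0)
    p = ws.u_high_probs(state.log_lambda, state.beta_z, state.phi)
    return float(p[i])


def update_phi(
    u_vector: np.ndarray,
    prior: PriorSpec,
    rng: np.random.Generator,
    coding: Coding = Coding.ZERO_ONE,
) -> float:
    """Conjugate Beta draw for the prevalence of the high confounder level."""
    _, hi = coding.levels
    m = int(np.sum(u_vector == hi))
    n = len(u_vector)
    return float(rng.beta(prior.a_phi + m, prior.b_phi + n - m))


def update_outcome_params(
    state: SamplerState,
    ws: _LikelihoodWorkspace,
    u: np.ndarray,
    prior: PriorSpec,
    proposal_sd: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[SamplerState, tuple[bool, bool]]:
    """One Metropolis step each for log lambda and beta_z (random-walk Gaussian)."""

    def log_prior(x: float) -> float:
        return -0.5 * (x - prior.mu0) ** 2 / prior.sigma0_sq

    ll, bz = state.log_lambda, state.beta_z
    accepted = [False, False]
    cur = ws.loglik_total(ll, bz, u) + log_prior(ll) + log_prior(bz)

    prop_ll = ll + proposal_sd[0] * rng.standard_normal()
    cand = ws.loglik_total(prop_ll, bz, u) + log_prior(prop_ll) + log_prior(bz)
    if np.log(rng.random()) < cand - cur:
        ll, cur, accepted[0] = prop_ll, cand, True

    prop_bz = bz + proposal_sd[1] * rng.standard_normal()
    cand = ws.loglik_total(ll, prop_bz, u) + log_prior(ll) + log_prior(prop_bz)
    if np.log(rng.random()) < cand - cur:
        bz, accepted[1] = prop_bz, True

    return SamplerState(ll, bz, state.phi), (accepted[0], accepted[1])


def _initial_state(cohort: Cohort, config: McmcConfig) -> SamplerState:
    if config.init is not None:
        return SamplerState(*config.init)
    events = float(cohort.event.sum())
    exposure = float(cohort.time.sum())
    log_lam = np.log(max(events, 0.5) / max(exposure, 1e-12))
    return SamplerState(float(log_lam), 0.0, 0.5)


def run_sampler(
    cohort: Cohort,
    pair: SensitivityPair,
    t0: float,
    prior: PriorSpec | None = None,
    config: McmcConfig | None = None,
) -> PosteriorDraws:
    """Systematic-scan Gibbs sampler for the augmented posterior.

    Parameters
    ----------
    cohort : Cohort
        Observed data; its coding must match ``pair.coding``.
    pair : SensitivityPair
        User-specified (alpha_u, beta_u) and prevalence prior.
    t0 : float
        Known change point of the delayed treatment effect, months.
    prior, config : optional
        Priors and chain settings; defaults are the vague priors and the
        5,000-iteration schedule.
    """
    prior = prior or PriorSpec()
    config = config or McmcConfig()
    if cohort.coding is not pair.coding:
        raise ValueError("cohort coding and sensitivity-pair coding must match")
    a_phi, b_phi = pair.prevalence_prior
    prior = PriorSpec(prior.mu0, prior.sigma0_sq, a_phi, b_phi)

    ws = _LikelihoodWorkspace(cohort, pair)
    ws.set_t0(t0)
    lo, hi = cohort.coding.levels
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))

    state = _initial_state(cohort, config)
    if not np.isfinite(ws.loglik_total(state.log_lambda, state.beta_z,
                                       np.full(cohort.n, lo))):
        bad = int(np.argmin(np.isfinite(
            ws.loglik_vector(state.log_lambda, state.beta_z, np.full(cohort.n, lo)))))
        raise ValueError(f"non-finite likelihood at initialisation (record {bad})")
    u = np.where(rng.random(cohort.n) < state.phi, hi, lo)

    n_iter, burn_in = config.n_iter, config.burn_in
    chains = {k: np.empty(n_iter) for k in ("log_lambda", "beta_z", "phi")}
    u_draws = np.empty((n_iter, cohort.n), dtype=np.int8)
    sd = list(config.proposal_sd)
    acc_counts = np.zeros(2)
    batch_counts = np.zeros(2)
    batch_size = 50

    for it in range(n_iter):
        p_hi = ws.u_high_probs(state.log_lambda, state.beta_z, state.phi)
        u = np.where(rng.random(cohort.n) < p_hi, hi, lo)
        state.phi = update_phi(u, prior, rng, cohort.coding)
        state, accepted = update_outcome_params(state, ws, u, prior, tuple(sd), rng)
        batch_counts += accepted
        if it >= burn_in:
            acc_counts += accepted
        elif config.adapt and (it + 1) % batch_size == 0:
            # Robbins-Monro style scale adaptation toward 0.44 acceptance,
            # active only during burn-in so post-burn-in kernels are fixed
            delta = min(0.1, 1.0 / np.sqrt((it + 1) / batch_size))
            for j in range(2):
                rate = batch_counts[j] / batch_size
                sd[j] *= np.exp(delta * (rate - 0.44) / 0.44)
            batch_counts[:] = 0.0
        chains["log_lambda"][it] = state.log_lambda
        chains["beta_z"][it] = state.beta_z
        chains["phi"][it] = state.phi
        u_draws[it] = u.astype(np.int8)

    kept = max(n_iter - burn_in, 1)
    acceptance = {
        "log_lambda": float(acc_counts[0] / kept),
        "beta_z": float(acc_counts[1] / kept),
    }
    ess = {}
    for k in chains:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess[k] = effective_sample_size(chains[k][burn_in:])
    return PosteriorDraws(
        log_lambda=chains["log_lambda"],
        beta_z=chains["beta_z"],
        phi=chains["phi"],
        u_draws=u_draws,
        acceptance=acceptance,
        ess=ess,
        coding=cohort.coding,
        burn_in=burn_in,
    )


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS from the autocorrelation sum with Geyer initial-monotone truncation.

    Returns 0 (with a warning) for a constant chain; never exceeds the chain
    length.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("chain too short for ESS estimation (need >= 10)")
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    if var == 0.0:
        warnings.warn("constant chain: ESS reported as 0", stacklevel=2)
        return 0.0
    # FFT autocovariance
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer: sum consecutive pairs, keep while positive and monotone nonincreasing
    m_max = (n - 1) // 2
    tau = rho[0]  # = 1
    prev = np.inf
    for m in range(m_max):
        gamma = rho[2 * m + 1] + (rho[2 * m + 2] if 2 * m + 2 < n else 0.0)
        if gamma <= 0:
            break
        gamma = min(gamma, prev)
        prev = gamma
        tau += 2.0 * gamma
    return float(min(n, n / max(tau, 1e-12)))


def export_chains(draws: PosteriorDraws, path, include_burn_in: bool = False) -> None:
    """Write the parameter chains as CSV (one row per retained iteration)."""
    import pandas as pd

    start = 0 if include_burn_in else draws.burn_in
    pd.DataFrame(
        {
            "iteration": np.arange(start, draws.n_iter),
            "log_lambda": draws.log_lambda[start:],
            "beta_z": draws.beta_z[start:],
            "phi": draws.phi[start:],
            "u_high_fraction": (
                draws.u_draws[start:] == max(draws.coding.levels)
            ).mean(axis=1),
        }
    ).to_csv(path, index=False)


def traceplot(draws: PosteriorDraws, path) -> None:
    """Trace plots for log lambda, beta_z and phi (burn-in shaded)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(7, 6), sharex=True)
    for ax, (name, chain) in zip(
        axes,
        (
            ("log lambda", draws.log_lambda),
            ("beta_z", draws.beta_z),
            ("phi", draws.phi),
        ),
    ):
        ax.plot(chain, lw=0.4)
        ax.axvspan(0, draws.burn_in, color="grey", alpha=0.15)
        ax.set_ylabel(name)
    axes[-1].set_xlabel("iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def extract_imputations(
    draws: PosteriorDraws,
    K: Optional[int] = None,
    burn_in: Optional[int] = None,
    thin: int = 1,
    pair: Optional[SensitivityPair] = None,
) -> ImputationSet:
    """Retain K post-burn-in, thinned u draws as imputations.

    Each imputation is paired with the same-iteration draws of phi, log lambda
    and beta_z. When K is smaller than the number of available draws, the K
    retained draws are spread evenly over the post-burn-in chain.
    """
    burn_in = draws.burn_in if burn_in is None else burn_in
    idx = np.arange(burn_in, draws.n_iter, thin)
    avail = len(idx)
    if K is None:
        K = avail
    if avail < K:
        raise ValueError(f"only {avail} post-burn-in draws available, need K={K}")
    if K < 1:
        raise ValueError("K must be >= 1")
    sel = idx if K == avail else idx[np.round(np.linspace(0, avail - 1, K)).astype(int)]
    return ImputationSet(
        u=draws.u_draws[sel].astype(float),
        phi=draws.phi[sel],
        log_lambda=draws.log_lambda[sel],
        beta_z=draws.beta_z[sel],
        pair=pair if pair is not None else SensitivityPair(0.0, 0.0),
    )
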