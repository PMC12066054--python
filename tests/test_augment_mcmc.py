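"""Correctness of the data-augmentation Gibbs sampler.

The binding checks are exact: the latent-confounder conditional is compared
against brute-force two-point enumeration of the unnormalised joint, the
prevalence update against Beta conjugacy, and the whole kernel against a
Geweke-style successive-conditional simulation whose stationary parameter
marginals must equal the prior.
"""

import math
import warnings

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import kstest

from rmstqba import (
    Coding,
    Cohort,
    McmcConfig,
    OutcomeParams,
    PriorSpec,
    SensitivityPair,
    effective_sample_size,
    extract_imputations,
    log_likelihood,
    run_sampler,
    treatment_prob,
)
from rmstqba.augment_mcmc import (
    SamplerState,
    _LikelihoodWorkspace,
    u_conditional_prob,
    update_outcome_params,
    update_phi,
)
from rmstqba.simulate import apply_admin_censoring, draw_event_time

from conftest import random_cohort


def enumeration_oracle(i, state, pair, cohort, t0):
    """Two-point enumeration of the unnormalised joint for subject i:
    outcome likelihood x propensity likelihood x Bernoulli(phi) prior."""
    outcome = OutcomeParams(state.log_lambda, state.beta_z, pair.beta_u, t0)
    rec = cohort.records[i]
    prop = pair.propensity()
    lo, hi = cohort.coding.levels
    logs = {}
    for level, prior_p in ((hi, state.phi), (lo, 1.0 - state.phi)):
        g = float(treatment_prob(level, prop))
        log_g = rec.arm * math.log(g) + (1 - rec.arm) * math.log(1.0 - g)
        logs[level] = log_likelihood(rec, level, outcome) + log_g + math.log(prior_p)
    return math.exp(logs[hi] - logsumexp([logs[hi], logs[lo]]))


class TestUConditional:
    def test_matches_enumeration_on_random_cohorts(self, rng):
        """Exact agreement with brute-force enumeration, 20 random cohorts."""
        for k in range(20):
            coding = Coding.ZERO_ONE if k % 2 == 0 else Coding.MINUS_PLUS_ONE
            cohort = random_cohort(rng, n=10, coding=coding)
            pair = SensitivityPair(
                alpha_u=float(rng.uniform(-1, 1)),
                beta_u=float(rng.uniform(-1, 1)),
                coding=coding,
                alpha0=float(rng.uniform(-0.5, 0.5)) if coding is Coding.ZERO_ONE else 0.0,
            )
            state = SamplerState(
                log_lambda=float(rng.uniform(-4, -1)),
                beta_z=float(rng.uniform(-1, 1)),
                phi=float(rng.uniform(0.05, 0.95)),
            )
            for i in range(cohort.n):
                got = u_conditional_prob(i, state, pair, cohort, outcome_t0=5.0)
                want = enumeration_oracle(i, state, pair, cohort, t0=5.0)
                assert abs(math.log(got) - math.log(want)) < 1e-10

    def test_no_information_returns_phi(self, rng):
        cohort = random_cohort(rng, n=8)
        pair = SensitivityPair(0.0, 0.0, coding=Coding.ZERO_ONE)
        state = SamplerState(-2.5, 0.0, 0.37)
        for i in range(cohort.n):
            assert u_conditional_prob(i, state, pair, cohort, 5.0) == pytest.approx(0.37)

    def test_strong_exposure_association_limit(self):
        # a strong exposure association forces u toward the level favouring the
        # observed arm: 0/1 coding with alpha0 = 0 saturates at
        # phi / (phi + (1 - phi)/2) since g(z=1|u=0) stays at 1/2 ...
        cohort = Cohort(time=[10.0, 8.0], event=[1, 1], arm=[1, 0])
        pair = SensitivityPair(25.0, 0.0, coding=Coding.ZERO_ONE, alpha0=0.0)
        state = SamplerState(-2.5, 0.0, 0.5)
        assert u_conditional_prob(0, state, pair, cohort, 5.0) == pytest.approx(2 / 3)
        # ... while under -1/+1 coding (g = expit(-alpha_u u)) the conditional
        # genuinely degenerates to 1
        cohort_pm = Cohort(
            time=[10.0, 8.0], event=[1, 1], arm=[1, 0], coding=Coding.MINUS_PLUS_ONE
        )
        pair_pm = SensitivityPair(-25.0, 0.0, coding=Coding.MINUS_PLUS_ONE)
        assert u_conditional_prob(0, state, pair_pm, cohort_pm, 5.0) > 1 - 1e-6


class TestPhiUpdate:
    def test_all_high_conjugate_moments(self, rng):
        u = np.ones(10)
        draws = [update_phi(u, PriorSpec(), rng) for _ in range(20_000)]
        # Beta(11, 1): mean 11/12, var 11/(144*13)
        assert np.mean(draws) == pytest.approx(11 / 12, abs=4 * math.sqrt(11 / (144 * 13) / 20_000))

    def test_none_high(self, rng):
        u = np.zeros(10)
        draws = np.array([update_phi(u, PriorSpec(), rng) for _ in range(20_000)])
        mean = 1 / 12  # Beta(1, 11)
        assert draws.mean() == pytest.approx(mean, abs=0.01)

    def test_minus_plus_coding_counts_high_level(self, rng):
        u = np.array([-1.0, 1.0, 1.0, -1.0, 1.0])
        draws = np.array(
            [update_phi(u, PriorSpec(), rng, Coding.MINUS_PLUS_ONE) for _ in range(20_000)]
        )
        assert draws.mean() == pytest.approx((1 + 3) / (2 + 5), abs=0.01)


class TestOutcomeParamUpdate:
    def test_tiny_proposal_keeps_chain_in_place(self, rng):
        cohort = random_cohort(rng, n=20)
        pair = SensitivityPair(0.3, 0.2, coding=Coding.ZERO_ONE)
        ws = _LikelihoodWorkspace(cohort, pair)
        ws.set_t0(5.0)
        state = SamplerState(-2.5, -0.3, 0.5)
        new, accepted = update_outcome_params(
            state, ws, np.zeros(20), PriorSpec(), (1e-12, 1e-12), rng
        )
        assert accepted == (True, True)
        assert new.log_lambda == pytest.approx(-2.5, abs=1e-10)
        assert new.beta_z == pytest.approx(-0.3, abs=1e-10)

    def test_degenerate_prior_collapses_to_prior_mean(self, rng):
        cohort = random_cohort(rng, n=20)
        pair = SensitivityPair(0.0, 0.0, coding=Coding.ZERO_ONE)
        ws = _LikelihoodWorkspace(cohort, pair)
        ws.set_t0(5.0)
        prior = PriorSpec(mu0=-2.0, sigma0_sq=1e-10)
        state = SamplerState(-2.0, -2.0, 0.5)
        for _ in range(200):
            state, _ = update_outcome_params(
                state, ws, np.zeros(20), prior, (0.05, 0.05), rng
            )
        assert state.log_lambda == pytest.approx(-2.0, abs=1e-3)
        assert state.beta_z == pytest.approx(-2.0, abs=1e-3)

    def test_recovers_treatment_effect_with_known_confounder(self, rng):
        """Posterior mean of beta_z near log(0.68) on a large cohort with the
        true confounder values plugged in."""
        from rmstqba import scenario, simulate_cohort

        spec = scenario("small1", math.log(0.5), n=2000, seed=77)
        cohort = simulate_cohort(spec)
        pair = SensitivityPair(
            spec.propensity.alpha1, spec.outcome.beta_u,
            coding=Coding.ZERO_ONE, alpha0=spec.propensity.alpha0,
        )
        ws = _LikelihoodWorkspace(cohort, pair)
        ws.set_t0(5.0)
        state = SamplerState(math.log(0.1), 0.0, 0.5)
        chain = []
        for it in range(3000):
            state, _ = update_outcome_params(
                state, ws, cohort.u_true, PriorSpec(), (0.06, 0.12), rng
            )
            if it >= 500:
                chain.append(state.beta_z)
        chain = np.asarray(chain)
        assert abs(chain.mean() - math.log(0.68)) < 2 * chain.std()


class TestRunSampler:
    def test_deterministic_given_seed(self, rng):
        cohort = random_cohort(rng, n=15)
        pair = SensitivityPair(0.3, -0.2, coding=Coding.ZERO_ONE)
        cfg = McmcConfig(n_iter=200, burn_in=50, seed=3)
        d1 = run_sampler(cohort, pair, 5.0, config=cfg)
        d2 = run_sampler(cohort, pair, 5.0, config=cfg)
        np.testing.assert_array_equal(d1.phi, d2.phi)
        np.testing.assert_array_equal(d1.u_draws, d2.u_draws)

    def test_coding_mismatch_rejected(self, rng):
        cohort = random_cohort(rng, n=6, coding=Coding.ZERO_ONE)
        pair = SensitivityPair(0.1, 0.1, coding=Coding.MINUS_PLUS_ONE)
        with pytest.raises(ValueError):
            run_sampler(cohort, pair, 5.0)

    def test_no_information_phi_marginal_is_prior(self, rng):
        """With beta_u = alpha_u = 0 the data carry no information on u, so the
        stationary phi marginal is its Beta(1,1) prior and each u_i's marginal
        frequency matches the posterior mean of phi."""
        n = 20
        cohort = Cohort(
            time=rng.exponential(10, n), event=np.ones(n, int),
            arm=rng.integers(0, 2, n),
        )
        pair = SensitivityPair(0.0, 0.0, coding=Coding.ZERO_ONE)
        cfg = McmcConfig(n_iter=22_000, burn_in=2000, seed=4)
        d = run_sampler(cohort, pair, 5.0, config=cfg)
        phi = d.phi[2000::20][:1000]
        assert kstest(phi, "uniform").statistic < 0.05
        u_marg = (d.u_draws[2000:] == 1).mean(axis=0)
        assert np.allclose(u_marg, d.phi[2000:].mean(), atol=0.02)

    def test_imputation_frequency_monotone_in_prior_mean(self, rng):
        n = 15
        cohort = Cohort(
            time=rng.exponential(10, n), event=np.ones(n, int),
            arm=rng.integers(0, 2, n),
        )
        means = []
        for a, b in ((2.0, 8.0), (5.0, 5.0), (8.0, 2.0)):
            pair = SensitivityPair(
                0.0, 0.0, coding=Coding.ZERO_ONE, prevalence_prior=(a, b)
            )
            d = run_sampler(
                cohort, pair, 5.0, config=McmcConfig(n_iter=4000, burn_in=500, seed=8)
            )
            means.append(float((d.u_draws[500:] == 1).mean()))
        assert means[0] < means[1] < means[2]

    def test_geweke_successive_conditional(self):
        """Alternating one Gibbs sweep with re-simulation of the data leaves the
        prior invariant: parameter chain moments must match the prior within
        Monte Carlo error."""
        rng = np.random.default_rng(7)
        n = 5
        arm = np.array([1, 1, 1, 0, 0])
        prior = PriorSpec(mu0=math.log(0.1), sigma0_sq=0.09, a_phi=2, b_phi=2)
        pair = SensitivityPair(0.4, 0.3, coding=Coding.ZERO_ONE)
        t0, T = 5.0, 48.0

        def simulate_data(state, u):
            outcome = OutcomeParams(state.log_lambda, state.beta_z, pair.beta_u, t0)
            tev = draw_event_time(arm, u, outcome, rng)
            time_, ev = apply_admin_censoring(tev, T)
            return Cohort(time=time_, event=ev, arm=arm, u_true=u)

        sd0 = math.sqrt(prior.sigma0_sq)
        state = SamplerState(
            prior.mu0 + sd0 * rng.standard_normal(),
            prior.mu0 + sd0 * rng.standard_normal(),
            float(rng.beta(2, 2)),
        )
        u = np.where(rng.random(n) < state.phi, 1.0, 0.0)
        cohort = simulate_data(state, u)
        iters, burn = 6000, 500
        chains = {k: np.empty(iters) for k in ("log_lambda", "beta_z", "phi")}
        for it in range(iters):
            ws = _LikelihoodWorkspace(cohort, pair)
            ws.set_t0(t0)
            p_hi = ws.u_high_probs(state.log_lambda, state.beta_z, state.phi)
            u = np.where(rng.random(n) < p_hi, 1.0, 0.0)
            state.phi = update_phi(u, prior, rng)
            for _ in range(3):
                state, _ = update_outcome_params(state, ws, u, prior, (0.3, 0.3), rng)
            cohort = simulate_data(state, u)
            chains["log_lambda"][it] = state.log_lambda
            chains["beta_z"][it] = state.beta_z
            chains["phi"][it] = state.phi
        for name, expected in (("log_lambda", prior.mu0), ("beta_z", prior.mu0),
                               ("phi", 0.5)):
            ch = chains[name][burn:]
            mcse = ch.std() / math.sqrt(effective_sample_size(ch))
            assert abs(ch.mean() - expected) < 3 * mcse, name


class TestEffectiveSampleSize:
    def test_iid_chain(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert effective_sample_size(x) == pytest.approx(1000, rel=0.2)

    def test_ar1_chain(self):
        rho = 0.9
        rng = np.random.default_rng(1)
        n = 50_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.3)

    def test_constant_chain_warns_zero(self):
        with pytest.warns(UserWarning):
            assert effective_sample_size(np.ones(100)) == 0.0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(5.0))

    def test_never_exceeds_length(self, rng):
        for _ in range(5):
            x = rng.standard_normal(200)
            assert effective_sample_size(x) <= 200


class TestExtractImputations:
    def _draws(self, rng, n_iter=100, burn=40):
        cohort = random_cohort(rng, n=8)
        pair = SensitivityPair(0.2, 0.2, coding=Coding.ZERO_ONE)
        return run_sampler(
            cohort, pair, 5.0, config=McmcConfig(n_iter=n_iter, burn_in=burn, seed=0)
        )

    def test_counts_and_pairing(self, rng):
        d = self._draws(rng)
        imps = extract_imputations(d, K=60)
        assert imps.K == 60
        assert imps.phi.shape == (60,)
        # imputation rows are actual sampler draws, parameters from same iterations
        assert set(np.unique(imps.u)).issubset({0.0, 1.0})

    def test_all_available_and_thinning(self, rng):
        d = self._draws(rng)
        assert extract_imputations(d).K == 60
        assert extract_imputations(d, thin=2).K == 30

    def test_insufficient_draws(self, rng):
        d = self._draws(rng)
        with pytest.raises(ValueError):
            extract_imputations(d, K=61)

    def test_default_schedule_leaves_1000(self, rng):
        # 5000 total with burn-in 4000 leaves 1000 imputations
        cfg = McmcConfig()
        assert (cfg.n_iter - cfg.burn_in) // cfg.thin == 1000
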