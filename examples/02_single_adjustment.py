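"""Impute the unmeasured confounder and adjust the dRMST at one grid point.

The two-step analysis at the data-generating associations: a Gibbs sampler
imputes the latent confounder given (alpha_u, beta_u), each imputation yields
an IPT-weighted dRMST, and Rubin's rules pool the K estimates.
"""

import math

import numpy as np

from rmstqba import (
    actual_drmst,
    adjusted_drmst_imputations,
    adjusted_drmst_true,
    extract_imputations,
    pool,
    run_sampler,
    scenario,
    simulate_cohort,
)
from rmstqba.sim_study import _true_pair

spec = scenario("small1", beta_u=math.log(0.5), n=300, seed=11)
cohort = simulate_cohort(spec)
pair = _true_pair(spec)  # the true associations, here assumed known

draws = run_sampler(cohort, pair, t0=spec.outcome.t0)  # 5000 draws, 4000 burn-in
imps = extract_imputations(draws, pair=pair)  # K = 1000 imputations
gammas, etas = adjusted_drmst_imputations(cohort, imps, tau=48.0)
pooled = pool(gammas, etas)

truth = adjusted_drmst_true(spec.outcome, spec.prevalence, 48.0)
oracle = actual_drmst(cohort, pair, 48.0)  # weights from the true u

print(f"true adjusted dRMST        : {truth:.2f} months")
print(
    f"imputation-based adjustment: {pooled.gamma_hat:.2f} months "
    f"(95% CI {pooled.ci_low:.2f} to {pooled.ci_high:.2f}, K={pooled.K})"
)
print(f"adjustment with actual u   : {oracle.gamma:.2f} months")
print(f"sampler ESS                : "
      + ", ".join(f"{k}={v:.0f}" for k, v in draws.ess.items()))
print(
    "The pooled estimate recovers the truth about as well as adjusting on\n"
    "the actual confounder; the wider interval reflects imputation\n"
    "uncertainty propagated through Rubin's rules (between-imputation\n"
    f"variance {np.var(gammas, ddof=1):.3f} months^2)."
)
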