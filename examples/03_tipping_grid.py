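"""Tipping-point analysis: how strong must unmeasured confounding be to
nullify a survival benefit?

A small two-arm cohort (29 vs 20 subjects, delayed treatment effect from 5
months) shows a significant unadjusted dRMST. The grid sweeps the
confounder-exposure association alpha_u and the confounder-outcome
association beta_u under the -1/+1 coding; cells whose pooled 95% CI covers
zero form the tipping set.
"""

import math

import numpy as np

from rmstqba import (
    Coding,
    Cohort,
    GridSpec,
    McmcConfig,
    OutcomeParams,
    naive_drmst,
    run_grid,
    tipping_set,
)
from rmstqba.simulate import apply_admin_censoring, draw_event_time

# simulated stand-in for a small external-control-arm comparison
rng = np.random.default_rng(6)
arm = np.r_[np.ones(29, int), np.zeros(20, int)]
u = np.where(rng.random(49) < np.where(arm == 1, 0.65, 0.35), 1.0, -1.0)
outcome = OutcomeParams(math.log(0.073), math.log(0.3), 0.3, t0=5.0)
t = draw_event_time(arm, u, outcome, rng)
time, event = apply_admin_censoring(t, 48.0)
cohort = Cohort(time=time, event=event, arm=arm, coding=Coding.MINUS_PLUS_ONE)

ref = naive_drmst(cohort, tau=48.0)
print(
    f"reference dRMST (no unmeasured confounding): {ref.gamma:.2f} months "
    f"(95% CI {ref.ci_low:.2f} to {ref.ci_high:.2f})"
)

spec = GridSpec(
    alpha_values=(-0.6, -0.3, 0.0, 0.3, 0.6),
    beta_values=(-0.8, -0.4, 0.0, 0.4, 0.8),
    mcmc=McmcConfig(n_iter=2000, burn_in=1000),
    seed=3,
)
result = run_grid(cohort, spec)
tips = tipping_set(result)

print(f"grid cells analysed: {len(result.cells)}")
print(f"nullifying scenarios: {len(tips)}")
for _, row in tips[tips["boundary"]].iterrows():
    print(
        f"  tipping at alpha_u={row['alpha_u']:+.1f} "
        f"(OR between levels {row['or_between_levels']:.2f}), "
        f"beta_u={row['beta_u']:+.1f} "
        f"(HR between levels {row['hr_u_between_levels']:.2f})"
    )
print(
    "Each boundary row is the weakest outcome association that, combined\n"
    "with that exposure association, renders the adjusted dRMST CI\n"
    "inclusive of zero. If such confounders are implausible in context, the\n"
    "finding is robust to unmeasured confounding."
)
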