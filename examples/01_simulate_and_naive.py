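"""Simulate a confounded cohort and see the bias of the naive comparison.

A binary confounder halves the hazard (beta_u = log 0.5) and makes treatment
more likely (Pr(z=1|u=1) = 0.6 vs 0.4): the treated arm is enriched with
good-prognosis patients, so ignoring the confounder overstates the benefit.
"""

import math

from rmstqba import adjusted_drmst_true, naive_drmst, scenario, simulate_cohort

spec = scenario("small1", beta_u=math.log(0.5), n=300, seed=7)
cohort = simulate_cohort(spec)
truth = adjusted_drmst_true(spec.outcome, spec.prevalence, tau=48.0)
est = naive_drmst(cohort, tau=48.0)

print(f"true adjusted dRMST : {truth:.2f} months")
print(
    f"naive dRMST         : {est.gamma:.2f} months "
    f"(95% CI {est.ci_low:.2f} to {est.ci_high:.2f})"
)
print(
    "The naive estimate ignores the confounder; over repeated cohorts it is\n"
    "biased upward relative to the true adjusted difference in restricted\n"
    "mean survival time up to 48 months."
)
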