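"""Small method-comparison study: imputed vs actual vs naive adjustment.

Repeated confounded cohorts are simulated from the delayed-effect model and
the dRMST is estimated three ways; bias, empirical SE and 95% CI coverage are
reported against the closed-form truth. A scaled-down run (20 replicates of
one scenario) keeps this example quick; the full study uses 100 replicates of
all eight scenarios.
"""

import math

from rmstqba import McmcConfig, StudySpec, table2_replicate

study = StudySpec(
    scenarios=(("small1", math.log(0.5)),),
    n_reps=20,
    n=300,
    mcmc=McmcConfig(n_iter=2500, burn_in=1500),
    seed=2,
)
report = table2_replicate(study)
print(report.round(3).to_string(index=False))
print(
    "\nThe imputation-based estimator tracks the truth about as closely as\n"
    "adjustment on the actual confounder (similar bias), at the cost of a\n"
    "slightly larger SE; the naive estimator is clearly biased."
)
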