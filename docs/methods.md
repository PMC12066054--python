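# Methods

This note records the models, estimators, numerical choices and limitations
behind `rmstqba`, at the level of detail a user auditing a sensitivity
analysis would need.

## Estimand

The target is the difference in restricted mean survival time,
dRMST(τ) = ∫₀^τ [S₁(t) − S₀(t)] dt, adjusted for a binary confounder u:
E_u[RMST(z=1, u) − RMST(z=0, u)] with u ~ Bernoulli(prevalence). Because it
integrates the survival curves rather than summarising a hazard ratio, the
estimand is meaningful under any pattern of non-proportional hazards. All
times are in months; τ defaults to the administrative censoring time of the
study (48 months in the packaged study conditions).

## Outcome and propensity models

The outcome model is piecewise exponential with a delayed treatment effect:

    h(t | z, u) = λ exp(u β_u + 1(t > t₀) z β_z).

The change-point indicator is strict: `t == t0` belongs to the pre-effect
segment, so survival is continuous at t₀ and the two arms are
indistinguishable up to and including it. Survival, the log likelihood
(δ log h − H with H the cumulative hazard), and the RMST all have closed
forms as sums of at most two exponential segments; `rmst_true` uses `expm1`
for numerical stability at small rates and returns exactly τ in the
no-event limit.

Treatment assignment is logistic. Two codings of u are supported by one
enum, and all likelihood code consumes the coded value directly:

* **{0, 1}** (simulation convention): Pr(z=1|u) = logit⁻¹(α₀ + α₁ u).
* **{−1, +1}** (empirical convention): the intercept is absorbed by the
  symmetric coding and forced to zero; Pr(z=1|u) = logit⁻¹(−α_u u).

Under the −1/+1 coding the two confounder levels differ by two units, so the
between-level exposure odds ratio is exp(2α_u) and the between-level hazard
ratio exp(2β_u), while the per-unit factors are exp(α_u) and exp(β_u). Both
conventions are reported side by side in every grid export
(`or_between_levels` / `or_per_unit`, `hr_u_between_levels` /
`hr_u_per_unit`); neither is silently preferred, since both appear in
applied reporting and they differ by a square.

Measured covariates enter the interfaces as optional arrays but the packaged
analyses use none: the study conditions isolate unmeasured confounding.

## Synthetic data generator

`simulate` draws u ~ Bernoulli(prevalence) (default 0.5), assigns treatment
from the logistic model, samples event times by exact inverse-CDF inversion
of the piecewise-exponential cumulative hazard (draw E ~ Exp(1); treated
subjects whose accumulated hazard passes r·t₀ switch to the post-effect
rate), and applies administrative censoring at T. Ties at exactly T count as
events; censoring applies only beyond T (the convention had to be fixed
somewhere and the boundary has probability zero under the continuous model).
Four named imbalance presets set (α₀, α₁) so that Pr(z=1|u=1)/Pr(z=1|u=0)
is 0.6/0.4, 0.4/0.6, 0.8/0.2 or 0.2/0.8; defaults N = 300, λ = 0.073/month,
β_z = log 0.68, t₀ = 5, T = 48 are the packaged study conditions, under
which the true adjusted dRMST is 3.59 months for β_u = log 0.5 and 2.36 for
β_u = log 2 (computed, not assumed, by `adjusted_drmst_true`).

Each cohort derives three deterministic sub-streams (confounder, treatment,
event times) from one root seed, so extending a later stage never perturbs
earlier draws. What the generator does **not** emulate: random or
covariate-dependent censoring, measured covariates, continuous confounders,
and model misspecification — passing tests show the machinery recovers the
estimand when the working model is the data-generating model, which is the
within-scope question for a sensitivity-analysis tool, not that the model
fits any particular real dataset.

## Sampler

The joint posterior over (log λ, β_z, φ, u₁…u_N) given (α_u, β_u) is sampled
by systematic-scan Metropolis-within-Gibbs:

* **u-block.** Each u_i's full conditional is an exact two-point Bernoulli
  computed on the log scale: outcome likelihood × propensity likelihood ×
  Bernoulli(φ) prior at each level, combined through a numerically safe
  logistic difference. The conditionals depend only on the shared parameters
  and subject i's own record, so all N are updated simultaneously as one
  valid Gibbs block (this is what makes 100-replicate studies cheap).
* **φ.** Conjugate Beta(a + m, b + N − m) with m the count of high-level u.
* **log λ, β_z.** One Gaussian random-walk Metropolis step each. Proposal
  scales adapt toward 0.44 acceptance in batches of 50 during burn-in only
  (Robbins–Monro-style decaying step), and are frozen afterwards so the
  post-burn-in kernel satisfies detailed balance exactly.

Defaults: 5,000 iterations, burn-in 4,000, thin 1, leaving K = 1,000
imputations; priors log λ, β_z ~ N(0, 100), φ ~ Beta(1, 1). Initialisation
is method-of-moments (log λ = log(Σδ/Σt)), β_z = 0, φ = 0.5, u from its
prior; an explicit (log λ, β_z, φ) warm start can be supplied. With no
measured covariates the propensity has no unknown parameters, so it
contributes a fixed factor to each u-conditional and needs no sampling.

Correctness is tested three ways: exact agreement of the u-conditional with
brute-force enumeration; the no-information limit (β_u = α_u = 0), where the
φ marginal must equal its Beta prior and every u-marginal the posterior mean
of φ; and a Geweke-style successive-conditional simulation (alternating a
Gibbs sweep with re-simulation of the data) whose stationary parameter
moments must match the prior within Monte Carlo error.

ESS is the autocorrelation-sum estimator with Geyer initial-monotone
truncation, clipped at the chain length; a constant chain reports 0 with a
warning. Any monitored parameter with ESS < 100 triggers a prominent
warning in grid runs (φ is typically the slowest-mixing parameter, and
binary u-chains typically the fastest).

## Weighted estimation

IPT weights are the unstabilised reciprocals w_i = 1/g for treated and
1/(1−g) for controls; scores at 0 or 1 raise an error rather than silently
producing infinite weights. Stabilisation and trimming are deliberately off
by default — the packaged analyses use moderate association grids where
weights stay bounded — and extreme-weight diagnostics should precede any
interpretation at aggressive grid points.

The weighted Kaplan–Meier estimator uses weighted event totals d_j and
at-risk totals Y_j with tied times sharing one jump and censorings at t
remaining at risk at t (the standard convention; events precede censorings
at ties). The RMST is the exact area of the step function on [0, τ], with
the curve extended flat beyond the last observed time; events after τ
cannot affect it. The per-imputation analysis is vectorized: times, events
and arms are shared across imputations, so all K weighted curves reduce to
a handful of array reductions over a (K × N) weight matrix. The same kernel
drives the bootstrap (a resample is a multinomial multiplicity applied to
each weight row).

**Variance.** Each arm's RMST variance is a Greenwood-type plug-in,
Σ_j c_j⁻¹ · d_j/(Y_j(Y_j − d_j)) · (∫_{t_j}^τ Ŝ du)², arms summed as
independent. The factor c_j = Y_j/Σ_{at risk} w_i² deflates the weighted
counts to the risk set's Kish effective sample size: weighted totals
overstate the information in the risk set (a weight-w subject is one
observation, not w), and without the correction the plug-in underestimates
by the design effect — a factor of 2–3 at the packaged imbalance scenarios.
With unit weights c_j = 1 and the formula is the classical Greenwood
expression; the correction also makes the variance invariant to rescaling
all weights. The binding validation is empirical: the plug-in agrees with a
B = 2,000 stratified nonparametric bootstrap within 20% across the study
configurations (ratios 0.90–1.01 in the packaged checks). A risk set
exhausted at an event time (Y_j = d_j with area still remaining) has its
term skipped with a warning. Known caution: under strongly asymmetric
exposure distributions this class of estimator can miss nominal coverage;
interpret extreme-grid-point CIs accordingly.

## Pooling

The pooled point estimate is the arithmetic mean of the K per-imputation
estimates and the pooled variance is W + (1 + 1/K)B (W the mean
within-imputation variance, B the between-imputation sample variance) —
Rubin's rules as standardly stated. Intervals use Student's t. The degrees
of freedom follow the Barnard–Rubin small-sample adjustment,
ν = (ν_old⁻¹ + ν_obs⁻¹)⁻¹, with the complete-data df taken from the Kish
effective sample size of the IPT weights summed over arms (minus one mean
per arm): with K = 1,000 highly similar imputations the classic Rubin df can
exceed any complete-data information bound, which the adjustment caps. The
classic rule is available via `rule="rubin"`. Zero between-variance yields
infinite df and a normal interval. Significance is defined as the CI
excluding zero.

## Grid driver

Cells are traversed with α_u as the outer loop and β_u ascending inside;
within a row each sampler warm-starts from the previous cell's posterior
means (first cell of each row cold-starts). Warm starts affect burn-in
efficiency only, not the target distribution — warm and cold grids agree
within Monte Carlo error, which the tests assert. Per-cell seeds derive from
(root seed, cell index) via `SeedSequence`, so any cell is reproducible in
isolation; a failed cell is recorded and the grid continues. The reference
estimate is the unadjusted (naive) analysis of the input cohort. The
tipping set is the non-significant cells, with a per-row boundary flag on
the minimal-|β_u| member; if the reference itself is non-significant every
cell is flagged and a warning emitted. At (α_u, β_u) = (0, 0) the weights
are identically 1, so the null cell equals the reference exactly.

## Problem sizes in the packaged checks

The method-comparison study runs at its full size — 100 replicates of
N = 300 with the default 5,000-iteration schedule — for the primary
scenario; the remaining scenarios are exercised at reduced replicate counts
in unit tests, which suffices because the estimator code paths are identical
across scenarios. Grid checks use 3×3–5×5 grids with 1,200–2,500-iteration
chains on cohorts of 40–120 subjects: grid behaviour is cell-wise
independent, so cell count stresses nothing the small grids do not. The
empirical-style workflow is demonstrated on a simulated 49-subject (29 vs
20) cohort with a delayed effect at 5 months, mirroring the scale at which
such external-control analyses arise in practice.

## Known limitations

* Binary confounder only; a continuous confounder summarising several
  unmeasured factors is plausible in applications but out of scope here.
* One parametric outcome family (piecewise-exponential delayed effect);
  spline baselines, cure fractions and time-varying effects would need new
  likelihood code, though the sampler and adjustment layers are agnostic to
  the form of the outcome log likelihood.
* Random-walk Metropolis mixes slowly for (log λ, φ) on small cohorts
  (ESS warnings are expected there); the imputation-quality checks gate on
  the u-chains, which mix fast because each u_i is refreshed exactly from
  its conditional every sweep.
* IPT weighting only; matching-based adjustment is not implemented.
* The tipping analysis inherits the interpretive caveats of all QBA:
  plausibility of the flagged (α_u, β_u) pairs must be argued from subject
  matter, e.g. by benchmarking against measured prognostic factors.
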