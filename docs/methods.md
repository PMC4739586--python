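# Methods

## Scope and data model

`wardaudit` analyses one admission-level table: a binary outcome (death
within 30 days of discharge), patient covariates (integer age, 18 binary
comorbidity-history indicators, a four-level sex-by-ethnic-origin category),
and two strictly nested cluster labels (ward within hospital, validated on
construction). Cluster identifiers are opaque strings; integer coding is
never assumed. Missing covariate values are rejected, not imputed — the
analysis the package reproduces reported no missingness handling, and
silent imputation would change the estimand.

### Exclusion cascade

`apply_exclusions` runs four steps in a fixed order: age window (45–80),
prior heart-failure diagnosis, nursing-home facility, then hospitals whose
*remaining* patient count falls below 50. The hospital-size floor is
evaluated after the patient-level filters because the flow diagram being
emulated lists it last; the test suite pins this order with a table where
the order changes the result. Each step's removal count is recorded in the
cohort's provenance and exportable as a JSON flow report. The source flow
diagram does not state on which table the <50 rule was counted; counting it
post-filter is this package's documented choice.

## Risk score

Case mix is condensed into a risk score: a single-level logistic regression
of the outcome on age (linear) and the comorbidity flags, reduced by
backward elimination — at each step the predictor with the largest Wald
p-value is dropped while that p-value exceeds `alpha_remove`. The source
analysis says only "stepwise backward"; Wald elimination at 0.05 is the
conventional reading and both criterion threshold and candidate set are
arguments. The fitted probabilities are cut into decile groups on the
fitting cohort (9 quantile cut points; ties at a cut assigned to the lower
group, deterministically), and the decile labels — not the continuous score
— enter all downstream models. The score is an internal adjustment; it is
not a transportable prediction rule and the package does not validate it
out-of-sample.

## Multilevel estimation

The three-level model is a logistic regression with two nested Gaussian
random intercepts on the logit scale. Two backends share one results
contract:

**Laplace (default, deterministic).** For fixed variances the joint mode of
(β, u) is found by penalized IRLS (full Newton with step halving). Under
strict nesting the random-effect block of the joint Hessian is block-arrow:
wards are diagonal and couple only to their own hospital, so each Newton
solve and the log-determinant cost O(#wards + #hospitals) via a Schur
complement that stays diagonal on hospitals. The Laplace-approximate
profile likelihood is maximized over (log σ²_h, log σ²_w) by Nelder–Mead.
This is the same approximation lme4's `glmer` (nAGQ = 1) uses, and one test
cross-checks against it through `Rscript`. Fixed-effect covariance is the
inverse Schur complement at the mode (conditional on the variance
estimates, standard GLMM practice); variance 95% intervals are Wald on the
log-variance scale from central-difference curvature of the profile
deviance — near the boundary the curvature can vanish, in which case the
interval is reported conservatively wide. A variance estimate below 1e-4 is
reported as a near-zero boundary estimate with a flag, not an error.

**MCMC.** Metropolis-within-Gibbs started from the Laplace mode (mirroring
the original RIGLS-then-MCMC strategy): vectorized scalar random-walk
updates for all ward intercepts at once and all hospital intercepts at once
(each set is conditionally independent given the rest), a joint random-walk
update for β with the scaled Laplace covariance as proposal, and conjugate
inverse-gamma Gibbs draws for the two variances. Priors: flat on β,
Γ⁻¹(0.001, 0.001) on each variance — the MLwiN default diffuse prior, chosen
because the original supplementary settings are unavailable; both are
configurable. Proposal scales adapt during burn-in (targets 0.44 scalar /
0.234 vector). Defaults: 1,000 burn-in + 5,000 kept iterations. Reported:
posterior medians and percentile 95% credible intervals for β and the
variances; posterior means/SDs for the cluster residuals. Convergence is
checked with a split-chain R-hat (one chain split into four segments) on the
variance components at threshold 1.05; exceeding it raises by default
(`on_nonconvergence="warn"` downgrades). Near-zero variance components mix
slowly under the diffuse inverse-gamma prior — short test chains therefore
use `warn`.

**Shrunken residuals.** Empirical-Bayes cluster estimates û with, by
default, their posterior ("diagnostic") standard errors — the convention
behind caterpillar-plot intervals û ± 1.96·SE. The alternative
"comparative" SE, √(σ² − posterior variance), is exposed as an option
because the source does not say which it used; the two are complementary
(their squares sum to σ²).

**DIC.** The conditional deviance information criterion: D̄ + p_D with
p_D = D̄ − D(posterior means of β and u), deviance being the Bernoulli
deviance conditional on the cluster residuals. Conditional and marginal DIC
differ; the conditional form matches MLwiN's. DIC is defined only for MCMC
fits — a likelihood-based fit raises and points to AIC instead.

Single-level models (models 1–2) are fitted by maximum likelihood through
statsmodels GLM behind the same results class; their DIC, when the pipeline
runs in MCMC mode, comes from the same sampler with no random levels.

## Derived measures

With patient-level latent residual variance π²/3 ≈ 3.289868:

* `icc_latent`: ICC_h = σ²_h/(σ²_h+σ²_w+π²/3); the ward ICC's numerator is
  σ²_h + σ²_w — two patients on one ward share both intercepts. The
  ward-only numerator is available behind a warning; it answers a different
  question and does not reproduce the reference summary block.
* `mor`: exp(√(2σ²)·Φ⁻¹(0.75)); hospital MOR uses σ²_h, ward MOR uses
  σ²_h + σ²_w, the same cumulative convention.
* `pcv`: 100·(σ²_new − σ²_prev)/σ²_prev, negative when added covariates
  explain variance; undefined (raises) at σ²_prev = 0.
* `poor`: 100·Φ(−|β|/√(2σ²)), the probability that the cluster-pair-specific
  odds ratio for a cluster covariate opposes the average one when cluster
  effects are Gaussian; σ² is the variance at the covariate's own level
  (ward variance for ward-volume terms, hospital variance for hospital-type
  terms). The exact published formula sits in an unavailable appendix; this
  closed form reproduces all four published values and is validated against
  a Monte-Carlo pair simulation to 0.2 percentage points. At β = 0 the
  opposed-sign event is ill-defined; the function returns the symmetric
  limit 50 (and 0 for β ≠ 0, σ² = 0).

Summary-table rounding: ICC three decimals, MOR and PCV two, POOR whole
percent.

## Discriminatory accuracy

AUC is the Mann–Whitney concordance probability with half credit for ties,
computed from rank placements; its 95% CI and the paired CI for AUC
differences use DeLong's placement variance (no installed package exposes
these intervals). Prediction equations are η = x'β̂ plus any subset of the
level residuals; excluding a level zeroes its contribution and a record from
a cluster absent from the fit raises rather than silently scoring zero. AUC
is evaluated on the fitting cohort (apparent discrimination), exactly as the
audit design intends — the target is the general contextual effect, not
transportable prediction, and no cross-validation is performed; apparent
AUCs with fitted residuals are optimistic for prediction purposes.

## Synthetic cohorts

The generator runs the model forward. Defaults state the emulated world:

| quantity | default | source of the choice |
|---|---|---|
| hospitals | 41 municipal / 21 provincial / 9 regional | published design |
| wards per hospital (mean) | 4.0 / 9.4 / 22.7 by type | ≈565 wards, published allocation |
| patients per ward (mean) | 66 / 79 / 52 by type | ≈37k patients, published type shares |
| σ²_h, σ²_w | 0.013, 0.170 | published adjusted variances |
| age | truncated normal, mean 71, SD 8, window 45–80 | published moments |
| sex-ethnicity shares | 51/34/8/7 % | published composition |
| sex, volume, type effects | published odds ratios (log scale) | published association table |
| age + comorbidity effects | see `_default_comorbidities` | chosen so the fitted decile-10 vs 1 OR is ≈20 and the case-mix AUC ≈0.73, the published magnitudes |
| intercept | −3.51 | calibrated (`calibrate_intercept`) to 9% prevalence |

Ward counts are 1 + Poisson, so no ward is empty; ward-volume tertiles are
coded within the realized cohort. Comorbidity flags are independent
Bernoulli — the real comorbidity correlation structure is unknown, so a
green recovery test establishes correct estimation under the stated world,
not robustness to realistic case-mix dependence. Raw mode plants
prior-heart-failure, nursing-home and out-of-age admissions as mutually
exclusive per-record classes plus optional undersized hospitals, and records
the intended cascade counts in the truth bundle. One
`numpy.random.default_rng(seed)` drives all draws in a documented stream
order, so a seed pins the cohort byte-for-byte.

## Numerical choices and degenerate inputs

* Variance optimization is on the log scale, clipped at e^-14; estimates
  below 1e-4 carry a boundary flag.
* PIRLS weights are floored at 1e-12; Newton steps are halved up to 25
  times; the sampler refreshes η from scratch every 500 iterations to kill
  floating-point drift.
* League-table ties are broken by cluster id; decile ties go to the lower
  group; a risk score with all-identical predictions warns and assigns
  every record to group 1.
* An empty post-cascade cohort raises (`EmptyCohortError`), never a silent
  zero-row table; rank-deficient designs name the aliased columns.

## Known limitations

* Laplace variance estimates for rare binary outcomes in small clusters
  carry some bias (the hospital component, truly 0.013, is typically
  estimated low at 100 hospitals); the MCMC backend is preferred for
  reported intervals.
* Wald log-scale variance intervals are approximate near the boundary.
* AUC confidence intervals condition on the estimated residuals; the extra
  uncertainty from estimating û is not propagated.
* The generator does not model selective referral (sicker patients
  channelled to reputed hospitals) or correlated comorbidities; contextual
  coefficients it plants are therefore recovered under ideal confounding
  conditions.
* MOR/POOR interval estimation is available only by posterior propagation
  from an MCMC fit and is not validated against published intervals.
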