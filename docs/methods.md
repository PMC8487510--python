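# Methods

## The measurement model

Disability is treated as a one-dimensional latent trait θ measured by the
six Katz items, each with three ordered categories (0 none / 1 partial /
2 total limitation). We use Samejima's graded response model parameterized
through the at-or-above cumulative curves

P(Y ≥ k | θ) = logistic(α θ − κ_k), k ∈ {partial, total},

with boundary identities P(Y ≥ 0) = 1 and P(Y ≥ 3) = 0. This orientation
makes κ a location on the disability continuum: an item/level with smaller
κ is lost earlier. Category probabilities are successive differences of the
cumulative curves; the strict order κ_partial < κ_total is a structural
constraint enforced at construction (an unordered pair would give the
middle category negative probability), never silently clamped.
Log-probabilities are computed with `log_expit` and floored at −745 (the
log of the smallest positive normal double) so that extreme latent values
stay finite during sampling.

## The longitudinal model

For subject s at time t (years since the subject's first interview)

θ_st = γ0_s + γ1_s·t, γ1_s = γ1′_s + Z_s β,

where Z_s stacks sex, standardized baseline age, residence, standardized
education and marital status (binary codings: female = 1, rural = 1,
without spouse = 1). All six items at a visit share the same θ. The time
origin is the subject's first interview, so γ0_s is baseline disability.

Priors: γ0_s ~ N(0, 1) — this fixed prior anchors the location and scale of
the latent metric (no constraint is placed on item parameters and no
post-hoc rotation is applied); γ1′_s ~ N(μ, σ_slope²) hierarchically;
α_i ~ LogNormal(0, 1); κ_partial,i ~ N(0, 10²) with the gap
δ_i = κ_total,i − κ_partial,i ~ LogNormal(0, 1), enforcing the threshold
order by construction; μ, β_j ~ N(0, 10²); σ_slope ~ HalfNormal(5). All
scales are configurable (`PriorSettings`).

## Sampler

An adaptive Metropolis-within-Gibbs kernel with five blocks per sweep:

1. item parameters — componentwise random-walk proposals on
   (log α, κ_partial, log δ) per item;
2. subject intercepts γ0 — one simultaneous vector proposal (subjects are
   conditionally independent given the structural parameters), accepted
   per subject;
3. subject slopes — the state stores the total slope γ1_s = γ1′_s + Z_s β,
   updated like γ0 with prior N(μ + Z_s β, σ_slope²);
4. (μ, β) — an exact conjugate Gibbs draw from the normal linear model
   γ1 ~ N(μ + Zβ, σ_slope² I), which is valid because the panel likelihood
   depends on (μ, β) only through γ1. γ1′ = γ1 − Zβ is recovered for
   reporting; the posterior is identical to the γ1′ parameterization;
5. log σ_slope — scalar Metropolis with the half-normal prior and the
   log-transform Jacobian.

Proposal scales adapt toward an acceptance rate of 0.35 during burn-in
only (multiplicative updates every 25 sweeps, clipped to [10⁻³, 10]), so
retained draws come from a fixed kernel. Initialization: item parameters at
their prior medians (α = 1, κ_partial = 0, δ = 1), all subject effects and
regression coefficients at 0, σ_slope = 1. Chains are seeded from
independent streams spawned from a single seed; runs are bit-reproducible.
The default protocol is 2 chains of 1,000 retained draws after a 4,000
burn-in with thin 1; recovery experiments in the tests and acceptance
script use 2,000 + 2,000.

Summaries pool chains and report the posterior mean, posterior SD (the
"SE" column of the conventional reporting format), central 95% credible
interval using the linear-interpolation empirical quantile rule, and a
naive Monte-Carlo standard error to disambiguate the two notions of SE.
Subject-level states are tracked as running posterior means (full draws
are retained only on request, to bound memory). Convergence diagnostics
use classic split-R̂ (not rank-normalized, so separated chains diverge
without bound and are easy to threshold) and bulk effective sample size
via arviz; any structural parameter with R̂ > 1.05 or undefined R̂ triggers
a warning.

## Hierarchy outputs

The loss hierarchy is the ascending-κ order of the 12 (item, level)
thresholds; ties break by the canonical item order (bathing, dressing,
toileting, transferring, continence, feeding), partial before total.
Threshold gaps are differences of posterior means (posterior uncertainty
of a gap can be obtained from the chains but is not the default, since
gaps are conventionally reported as point values). Discrimination bands
follow the common logistic-metric table — none < 0.01 ≤ very_low < 0.35 ≤
low < 0.65 ≤ moderate < 1.35 ≤ high < 1.70 ≤ very_high, half-open on the
left — exposed as a configurable scheme enum, because published verbal
labels for these items are not internally consistent with any single
table. The applicability check requires α > 0.3 strictly for every item.

## Trajectory stage

Per-visit posterior-mean θ values are mapped affinely so the pooled
minimum lands at −3 and the maximum at +3 (order preserving; alternatives
such as fixed truncation or percentile mapping are deliberately not the
default, the min–max map being the simplest surjective choice), and each
visit is indexed by years before death = death time − visit time, so the
curves run from 19 years out (left) to death at 0. The mixed model

θ = Xβ_fixed + b1_s + b2_s·t + e, (b1, b2) ~ MVN(0, Σ), e ~ N(0, σ²)

is fitted by maximum likelihood (not REML) via statsmodels MixedLM; with
random effects disabled the fit reduces exactly to OLS. Default fixed
effects: intercept, time, sex, residence, marital, standardized age and
education, sex×residence and sex×marital. Group curves for the
sex×residence (MU/FU/MR/FR) and sex×marital (MY/FY/MN/FN) groupings
evaluate the fixed-effect prediction with non-grouping covariates at
their sample means; observed group means per integer year are emitted
alongside. Time interactions with the grouping can be added through the
term list (terms are products over `_x_`-joined factors).

Two caveats of this two-stage design: θ enters the regression as if
observed — its posterior uncertainty is ignored (a chain-resampling
propagation would be straightforward but is not the default) — and
because the LIRT posterior means are almost exactly linear in t per
subject, the mixed model can attribute nearly all variance to the random
effects, leaving a residual variance near zero. Both are properties of
the two-stage approach, not bugs.

## Synthetic cohort generator

The generator emulates a mixed-longitudinal cohort of decedents aged 60+:

- covariates: independent Bernoulli binaries (female 0.602, rural 0.631,
  without spouse 0.808), age ~ N(91.3, 9.6²) truncated below at 60,
  education ~ N(1.4, 2.9²) truncated at 0 (rejection sampling);
- follow-up: death ~ Exponential(mean 5.0 years) capped at 19; visits at
  0 and then every N(3.0, 0.5²) years (floored at 0.5) strictly before
  death. The exponential mean was calibrated once, analytically, so the
  wave-censored median follow-up is ≈ 3 years; the death law and jitter
  are simulation conveniences that mimic the follow-up distribution, not
  claims about any real survey's design. A fixed `n_visits` override
  produces balanced designs for recovery studies (death then follows the
  last visit);
- responses: θ built from γ0 ~ N(0, intercept_sd²) with intercept_sd = 1
  (anchoring the scale to the γ0 prior) and slopes with mean μ = 0.857,
  the reference covariate coefficients, and slope_sd = 0.3 — a value
  chosen once as realistic subject heterogeneity relative to the mean
  decline, since no dispersion is published; categories sampled from the
  GRM curves; responses blanked missing-completely-at-random at rate
  0.02 by default.

What the generator does **not** emulate: informative dropout or any
dependence of death on θ given covariates, covariate correlations (a
joint distribution is not published; binaries are independent), rolling
cohort replacement, and survey weights. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the stated
generating process, not robustness to those real-data features.

## Validation sizes and numerical choices

Recovery experiments use n = 500 subjects × 4 visits for threshold-order
recovery (Spearman ρ of the 12 posterior-mean κ's against truth, sign
agreement for |κ| > 0.5) and n = 1,000 for the mean slope μ, each with
2 chains × 2,000 retained draws after 2,000 burn-in; the mixed model uses
n = 300 × 5 visits. These sizes give stable recovery while keeping a full
validation run in minutes on one core. The panel log-likelihood is checked
against a brute-force double-loop oracle (with `softplus`-stable log
probabilities) to 10⁻⁹ on random small panels. Degenerate inputs error
rather than warp results: empty datasets, zero-variance covariates,
unordered thresholds, single-visit-only designs for the random slope,
rank-deficient fixed-effect designs (aliased columns are named), and
zero-range latent scores at the rescaling step.

## Data dialect

Responses: `subject_id, visit_time, item, category` and subjects:
`subject_id, sex, residence, marital, age_baseline, education, death_time`
as comma- or tab-delimited text (by extension); missing is an empty field
or `NA`, represented internally as a distinct missing state, never a
numeric code. Out-of-range categories are rejected, not coerced. Subjects
with unknown death time or without a single non-missing Katz response are
dropped at load with a warning; the inclusion filter additionally removes
subjects aged ≤ 60 at baseline and those with incomplete covariates,
reporting one count per reason (first applicable reason in the documented
precedence). Standardization of age and education uses the sample SD
(n − 1 denominator).
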