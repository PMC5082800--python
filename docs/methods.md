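# Methods

This note documents the statistical machinery of `linkedscore`: the
models it fits, the synthetic data it tests itself on, the numerical
choices, and what the tests do and do not establish.

## Exposure definition

Diagnostic codes — never medications — count toward a patient's
comorbidity burden when recorded **strictly before a cutoff two
calendar months before the index date** (configurable; six months as a
sensitivity setting).  The exclusion removes palliative and
end-of-life coding that would otherwise leak the outcome into the
exposure.  Window arithmetic is calendar-month based with day-of-month
overflow clamped to month end (31 March − 1 month = 28/29 February),
because cutoffs are stated as calendar dates.  Duplicate recordings
collapse to one exposure per (patient, code, care setting); recurrence
counts play no role in the score.  A separate indicator flags any
hospital event in `[index − 12 months, index − 2 months)` — recent
hospitalisation is itself prognostic and separates "coded in hospital"
from "recently hospitalised" in the weighting model.

Both terminologies are addressed by prefix: first character = chapter,
first two characters of the dot-stripped code = subchapter.  ICD-10
codes are normalized by removing dots (hospital data stores them
undotted); trailing filler dots of 5-byte Read codes are ignored.  A
partial mapping table sends ICD subchapters to Read subchapters; an
unmapped subchapter simply remains its own ICD-only group.

## Per-code screening

Every observed code gets one Cox proportional-hazards fit: its
indicator plus age (continuous, linear) and sex.  Codes never observed
before the cutoff, observed for every patient, or with monotone
likelihood are flagged (`status` column), not dropped silently.  The
fitter is a Newton–Raphson maximizer of the Efron partial likelihood
(Breslow optional) with step-halving, a gradient tolerance of 1e-8
scaled by the number of events, and counting-process entry times for
left-truncated episodes.  Standard errors come from the observed
information.  Implementation detail that matters for throughput: the
risk-set structure (event-time indices, difference-array boundaries,
tie groups) is computed once per fit, so each Newton iteration is a
handful of `bincount`/cumulative-sum passes — a few milliseconds per
code at n = 30,000 — and screening hundreds of codes is cheap.  The
fitter is cross-checked against an independent implementation
(lifelines) to ~1e-4 on coefficients and standard errors, including
under heavy ties and left truncation, and against a closed-form
grid-search oracle on a 3-subject dataset.

## The hierarchy

Screening estimates are re-estimated in a three-level normal-means
model:

    y_c      ~ Normal(theta_c, se_c^2)
    theta_c  ~ Normal(mu_sub(c), sigma_code^2)
    mu_sub   ~ Normal(mu_chap(sub), sigma_sub^2)
    mu_chap  ~ Normal(0, 1000^2)

ICD codes attach to their mapped Read subchapter where a mapping
exists, so both settings' codings of one disease share a group.  The
two-stage construction (per-code Cox summaries, then a normal-means
model on them) is the standard meta-analytic normal approximation to
the log hazard ratio; a joint survival MCMC over every code would add
nothing at this scale and cost hours.  Scale hyperparameters get
Half-Normal(0, 1) priors (the top-level prior is the only level whose
scale is fixed, at 1000 — flat for all purposes on the log-HR scale).

Sampling is by Gibbs, with two deliberate collapsings: `sigma_code` is
updated against the likelihood with `theta` integrated out
(y_c ~ N(mu_g, se_c² + sigma²)), and `sigma_sub`/`mu_chap` against the
group summaries with `mu_sub` also integrated out (m_g ~ N(mu_chap,
1/W_g + sigma_sub²)).  Without the second collapsing the all-null
regime exhibits the classic funnel — scales and group means lock each
other near zero and chains disagree (split-R-hat ≈ 1.45); with it,
R-hat ≈ 1.002 everywhere.  Scales are slice-sampled (stepping-out).
Defaults: 4 chains × (1,000 warmup + 1,000 draws), fixed seeds, error
raised if any monitored split-R-hat exceeds 1.05.  The sampler is
checked against the exact conjugate posterior in a fixed-variance
configuration and against the raw estimate for a single-member
hierarchy.

**Selection**: a code is kept when its central 99% credible interval,
or its subchapter group's, lies wholly above hazard ratio 1.2.  The
threshold is read one-sided (harmful direction): the score has no
protective categories, and a symmetric variant (interval below 1/1.2)
exists but is off by default.  Selection is monotone in the threshold.

## Categories and weights

Selected Read codes group by Read subchapter, selected ICD codes by
ICD subchapter; an ICD group whose mapped Read subchapter also formed a
group merges into a combined category.  Manual clinical review of the
groups is replaced by a declarative YAML override file (move/drop/
rename/merge operations applied in file order; the shipped default is
empty).

The weighting model is a single multivariable Cox fit: one indicator
per category **per source** (Read vs ICD), plus age, sex and the
recent-hospitalisation flag.  Categories whose two source coefficients
do not differ (Wald z on the coefficient difference with
sqrt(se_r² + se_i²), merge when p ≥ 0.005) are collapsed to one
"either source" indicator and the model refit; the remainder keep
separate weights — that is how hospital-specific weights arise.

Weights are `round(10·β)` with half-up ties.  Retention default:
β > 0 with the 99% interval excluding the null.  The stricter
"interval above HR 1.2" retention is available (`rule="hr12"`) but not
default, because the published table itself contains categories with
HR 1.1 and weight 1, which only the null-exclusion rule admits.
Weights can be capped (sensitivity setting 10; score totals are capped
at 20 in distribution comparisons).

## Scoring semantics

A category contributes to a patient's total at most once: via Read
codes it scores the read/combined weight; via ICD-10 codes the
ICD-specific weight when one exists (else the combined weight); via
both, the higher.  Totals are summed then capped.  Unknown codes are
counted and ignored — production dictionaries always outrun code
lists.  Comparator indices (Charlson, Elixhauser) run through the same
matcher with single weights per category; the packaged comparator
fixtures are *synthetic* code lists in the same CSV layout, suitable
for exercising the machinery, not for clinical use.  The packaged
published weight table likewise carries genuine category labels,
hazard ratios and weights, but synthetic stand-in member code lists.

## Validation machinery

Harrell's C counts usable pairs (the shorter follow-up ends in an
event; equal times unusable; tied scores ½) with Fenwick-tree
accumulation in O(n log n), and its standard error is the exact
leave-one-subject-out jackknife computed from per-subject pair counts,
with the normal-theory interval formed on the Somers'-D scale
(D = 2C − 1).  C is invariant under strictly monotone transformations
of the score and equals exhaustive pair counting on small data exactly.

Bootstrap optimism re-runs the *entire* model-building pipeline per
replicate: resample patients with replacement, refit, and take
C(refit score on resample) − C(refit score on original), averaged over
replicates.  A scoring rule fixed a priori shows optimism ≈ 0 (within
Monte Carlo error); a memorize-the-outcome pipeline shows large
positive optimism — both directions are asserted in tests.

Stratified discrimination re-computes C per stratum (age bands
20–29 … ≥90, consultation bands 0/1/2–3/4–7/8–13/≥14, deprivation
quintiles); follow-up-year strata condition on survival to the year's
start (left truncation) and censor at its end.  Condition adjustment
analyses fit the condition indicator plus adjusters, optionally
splitting follow-up at 60 days with window-specific condition terms;
the score used for adjustment is recomputed with the condition's own
category removed from the table.  Chronic conditions are flagged from
any pre-cutoff code; acute events re-anchor follow-up at the first
event, with comparators anchored at a random observed day of their own
follow-up.

## The synthetic linkage

The generator emulates the *structure* of a linked primary/secondary
care cohort: two terminologies with configurable chapter/subchapter/
code layout, a seeded injective partial ICD→Read subchapter mapping,
true effects defined at group level (a mapped pair shares one value)
with Normal(0, σ_c) code-level noise — exactly the exchangeability the
hierarchy assumes, so shrinkage is provably beneficial on-model; an
off-model mode draws independent per-code effects for robustness
checks.  Patient hazards are exponential (Weibull shape exposed):
rate = baseline · exp(0.085·(age − 60) + 0.15·male + Σ code effects),
with age ~ Normal(55, 18) clipped to [20, 100], transfer-out censoring
at 3%/year, five-year administrative follow-up, day-resolution times
(hence heavy ties, as in real EHR data), code prevalence logistic in
age (+0.02 logit/year, reproducing the confounding that makes age
adjustment matter), negative-binomial consultation counts that rise
with morbidity, and recurrent hospital recordings of owned codes.

The **desk-scale preset** (n = 30,000 by default) pins six non-null
combined groups at log-HRs evenly spaced on [0.3, 1.1] and calibrates
the baseline hazard (0.0097/year at age 60) so first-year mortality is
≈ 3.3%, the full-scale study's rate; full-scale numbers (657,264
people, 21,672 first-year deaths) are carried as metadata only.  Code
prevalence follows a **severity gradient** (odds × exp(−2.5·|group
effect|), base prevalence 4%): severe conditions are rare in real
populations, and without this the total comorbidity-burden variance is
so large that non-collapsibility attenuates univariable marginal
hazard ratios by 20–30%, which no analysis pipeline could undo.

What passing tests on this generator shows: the pipeline recovers
known subchapter-level effects through the whole screening → shrinkage
→ selection → weighting chain, controls false positives on null data,
and its optimism estimator is calibrated.  What they do not show:
robustness to real coding behaviour — code co-occurrence semantics,
calendar drift, differential ascertainment between practices, disease
natural histories — none of which the generator attempts.

## Statistical power at desk scale

One property of the full-scale study does not survive honest
downscaling: reliably *selecting* a category whose true log hazard
ratio is 0.3 (HR 1.35) under the "99% interval above 1.2" rule.  The
rule needs the group posterior's lower bound above log 1.2 ≈ 0.182,
a margin of 0.118; with the ~3,500 deaths a 30,000-patient cohort
yields in five years at 3.3%/year, the group-level standard error
floor is ≈ 0.03, making per-seed selection probability at most
~60–75% regardless of generator design (the source study's development
half, with ~11,000 first-year deaths among 328,628 people, sits near
se ≈ 0.02 and clears the bound).  Stronger effects (≥ 0.46) select
essentially always.  The recovery benchmark therefore measures the
fraction of category-instances recovered-with-accurate-weight over
10 seeds (observed ≈ 0.92; threshold 0.8) rather than demanding every
category in every seed, and the acceptance script reports the presence
and accuracy fractions separately.

## Numerical choices and degenerate inputs

- Ties: Efron default (day-resolution data), Breslow for oracle
  comparisons (the subject-duplication identity holds only under
  Breslow).
- Convergence: Newton–Raphson, step-halving, gradient tolerance
  1e-8 × events, 60 iterations; separation diagnosed either by a
  diverging coefficient during iteration or post-hoc (|β| > 10 with
  SE > 10) and reported with the covariate's name.
- Constant covariates, zero events, non-nested likelihood-ratio
  requests, overlapping strata, non-increasing cutpoints, negative
  caps: all rejected with named errors.
- All randomness flows from explicit seeds (generator, sampler chains,
  splits, bootstrap); identical configurations give byte-identical
  artifacts, which the pipeline manifest records.
- Test and benchmark problem sizes — n = 5,000 with ~200 codes for
  shrinkage calibration, n = 30,000 × 10 seeds for end-to-end
  recovery, B = 20 bootstrap replicates — were chosen as the smallest
  scales at which the respective properties are statistically
  decidable.

## Known limitations

- The packaged member code lists (score and comparators) are synthetic
  stand-ins; the published weights and labels are genuine.
- The derivation has no notion of practice-level clustering; the
  concordance CI clustering option the source analyses may have used
  is not implemented.
- The acute-condition mode takes precomputed event flags; multi-source
  case definitions (e.g. two-source concurrence for gastrointestinal
  bleeding) are out of scope.
- "Categorical" score use enters one indicator per attained value
  after capping at 20; no coarser binning is attempted.
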