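# Methods

## The design and its estimand

The package targets the individually matched case–control design nested in a
longitudinal cohort of women: a baseline questionnaire wave (ages 16–75), a
follow-up wave roughly eight years later that defines *new-onset* disease
(asthma reported at follow-up by a woman disease-free at baseline), and a
later exposure questionnaire measuring *lifetime* hormonal exposures. Each
new-onset case is matched to up to ten controls on exact age in years at
baseline, place of residence, and smoking status; controls must be
disease-free through follow-up. The estimand is the exposure odds ratio from
conditional logistic regression, which conditions on the matched set and
thereby eliminates stratum-specific nuisance intercepts: with one case per
stratum each stratum contributes `exp(x_case·β) / Σ_i exp(x_i·β)`. Because
the outcome is rare (well under 15% cumulative incidence), odds ratios are
read as risk ratios where the E-value calculus needs them; the code warns
when a simulated incidence violates that approximation.

## Synthetic cohort generator

The generator (`matchedcc.synthetic_cohort`) draws covariates with marginals
typical of a Scandinavian female population survey (uniform ages 16–75,
57% urban residence, 56/37/7% never/former/current smokers, BMI ~ N(25.5,
4.2²) banded at 25/30, menarche ~ N(13, 1.4²), menopause ~ N(51, 3.5²) for
women 45+). Ever-use of hormonal contraceptives follows an age profile
(higher in younger birth cohorts, 45–85% across ages) with start ages
uniform on 14–22 (median ≈ 18); menopausal hormone therapy has 17%
prevalence among women 45+ with start ages uniform on 48–56 (median ≈ 52).

Disease arises in two logistic stages sharing a per-woman normal frailty
(random intercept) `u ~ N(0, frailty_sd²)`:

* **pre-baseline stage** — cumulative risk of having developed asthma by the
  baseline wave, with a per-year age slope so older women carry more
  accumulated risk;
* **follow-up stage** — eight-year incidence after baseline.

The causal exposure effect (`true_logOR_exposure`) enters both stages when
the exposure started before the relevant window. This shared-frailty
two-stage structure is the minimal mechanism that produces *depletion of
susceptibles*: excluding women with prevalent disease at baseline removes
more high-frailty women from whichever exposure group had higher
pre-baseline risk, and the imbalance grows with baseline age.

Default rates are chosen once to sit at the scale of a 15,003-woman survey
wave: wave response probabilities 66% / 72% / (63% cases, 47% controls),
baseline asthma prevalence ≈ 11%, follow-up incidence ≈ 2%. The survey-scale
defaults are *not* powered to show the selection trend at Monte-Carlo
resolution; the demonstration scenario below exists for that purpose.

Item non-response is generated missing-at-random by construction (MCAR
rates, logistic MAR on observed covariates with a calibrated intercept, or
per-group rates such as differential exposure missingness by case status),
because chained-equation imputation assumes MAR. MNAR generation is out of
scope.

What the generator does **not** emulate: questionnaire measurement error and
recall bias, unit non-response that is informative for the exposure–outcome
relation, exposure subtype/dose/duration, and competing mortality. Passing
tests therefore validate the statistical machinery under MAR and a correctly
specified frailty structure, not robustness to those real-data features.

## Matching

Exact matching without replacement. Controls are pooled by the exact key;
each key's pool is given one seeded permutation, and cases (processed in
ascending age with seeded tie-breaks) take successive disjoint chunks of at
most `max_controls` ids. Chunking a single permutation has the same joint
distribution as sequential uniform draws without replacement and runs in
linear time at cohort scale. Cases with an empty pool are reported in an
`unmatched` list, never silently dropped; an optional ±k-year age caliper can
widen the pool. When a pool exhausts, *which* case goes unmatched depends on
the seeded processing order; the number of matchable strata does not.

## Multiple imputation

Fully conditional specification with family-per-variable conditionals:
Bayesian-draw ridge logistic (binary), ridge multinomial (nominal), and
predictive-mean matching with `donors_k = 5` (continuous/ordinal; imputed
values are always observed donor values, preserving support and skew).
Parameters are drawn from their approximate normal posterior before each
prediction so the imputations are proper. Visit order is monotone (least
missing first); starting values are random draws from the observed margin;
`m = 100` is the analysis default while the test/CI profile uses
`m = 5–10` with `n_iterations = 5–10` (with a single incomplete variable the
chain mixes in one sweep; pooled SEs differ only slightly from m = 100).
The ridge (1e-3) keeps perfectly separated conditionals finite — a warning-
level degradation, never a crash. Identifier columns (e.g. the stratum id)
are excluded from predictor sets via `ImputationModelSpec.exclude`; the
outcome and matching variables belong *in* the predictor sets for
compatibility with the conditional-logistic analysis model.

Convergence diagnostics regress the across-chain mean trace of each imputed
variable (second half of iterations) on iteration number; the trend z-score
uses whichever is larger of the residual noise and the between-chain
sampling noise of the mean, so short healthy runs are not flagged
spuriously. A single-iteration run cannot demonstrate convergence and is
always flagged.

## Frequentist conditional logistic regression

Newton–Raphson from β = 0 with step-halving. Two numerical guards matter at
large stratum counts: the score tolerance is floored at `1e-11 ×` the number
of design rows (the float64 accumulation noise of the score sums), and
step acceptance is relative to the magnitude of the log-likelihood, since
near the optimum a true improvement can be below the representable
resolution of a log-likelihood of order 10⁴. Covariates constant within
every stratum (the exact-matched variables — age is deliberately kept in the
default adjustment set) are reported as non-identified and dropped from
estimation rather than estimated; monotone likelihood (separation) is
flagged on the result. Wald intervals on the log scale. Rubin's rules pool
per-imputation fits (`T = W + (1 + 1/m)B`) with Barnard–Rubin degrees of
freedom; with m = 1 the pooled result equals the single fit. Complete-case
analysis drops rows listwise and then whole strata that lose their case or
all controls, with counts logged.

## Bayesian conditional logistic regression

The exposure coefficient takes an elicited normal prior; confounder
coefficients default to weakly informative N(0, 2.5²); a flat prior is the
improper uniform (posterior ∝ conditional likelihood, so its mode is the
MLE — used as a sampler calibration check). Elicited priors ship as
configuration: N(−0.26, 0.20²) for hormonal contraceptives, N(0.17, 0.13²)
for menopausal hormone therapy, both derivable from prior-study estimates
by inverse-variance pooling of log-ORs (the package's `pool_evidence`
implements that rule; `SE = (log hi − log lo)/3.92`).
The alternative-prior grid widens σ by {1.5, 2, 3} and shrinks μ toward 0 by
the same factor — a package choice expressing progressively weaker
commitment to the elicited direction, bracketed by the flat prior.

Sampling is adaptive random-walk Metropolis: proposal covariance from the
inverse curvature at the posterior mode scaled by 2.38²/d, global step size
Robbins–Monro-adapted to ~30% acceptance during warmup and frozen after.
Defaults: 4 chains × 1500 iterations, half warmup. Convergence is judged by
split-R̂ (< 1.01) and bulk ESS (> 400) on the exposure coefficient via
arviz; a failing R̂ flags the result rather than raising. Imputation
uncertainty is propagated by *mixing* equal numbers of post-warmup draws
across the m completed datasets — the mixture approximates the observed-data
posterior — rather than pooling point summaries. P(OR > 1) is the fraction
of mixed draws with positive exposure log-OR; the 95% central posterior
interval spans the 2.5th–97.5th percentiles.

## E-values

`E = RR* + sqrt(RR*(RR*−1))` with `RR* = max(RR, 1/RR)`; the CI E-value uses
the bound closer to the null and is 1 when the interval covers 1. Values are
reported to two decimals.

## Selection diagnostic and the demonstration scenario

`subgroup_trend` refits the analysis in nested subgroups of strata whose
case is at or above each age cutoff (default cutoffs 25, 35, 45, 55, 65).
Matching is exact on age, so subsetting strata by the case's baseline age
preserves matching validity. Subgroups with fewer than five informative
strata are flagged unstable but reported; empty subgroups are recorded as
not estimable. The monotone flag is strict non-decrease of the above-cutoff
point estimates.

`depletion_experiment` crosses true OR ∈ {0.6, 0.8, 1.0, 1.25} with frailty
on/off and exclusion on/off and tabulates bias by cutoff. The "exclusion
off" comparator sets pre-baseline risk to zero — a study that starts before
the exposure could deplete anyone — because with frailty on, merely skipping
the exclusion step leaves no well-defined incident-case set.

The canned demonstration (`demonstrate_selection_trend`) uses a
strong-selection scenario: protective true OR 0.5, frailty SD 2.5, and a
pre-baseline risk gradient steep enough that prevalence reaches ~35–50% in
the oldest cohorts (overall ≈ 11%, matching the scale of the emulated
survey), with follow-up incidence rising with age so that older strata are
well represented. The cohort size (2.8 million) is a Monte-Carlo resolution
choice: strict 5-point monotonicity of nested subgroup estimates demands
per-increment noise well below the bias increments, and the increments of
the normal-frailty mechanism are bounded (~0.05–0.09 log-OR per decade
before saturating — with a single normal frailty the differential depletion
peaks and then shrinks as both groups become fully depleted). The null arm
(harmful OR 1.5, no frailty, no exclusion, age-constant incidence) has no
mechanism and serves as the no-trend control. Two caveats are inherited from
the design itself: an age-*increasing* follow-up incidence combined with
frailty induces a small attenuation gradient even without exclusion (the
null arm therefore uses an age-constant incidence), and the diagnostic
demonstrates that the selection mechanism is *sufficient* to produce the
upward age trend, not that it is the only explanation (age effect
modification and age-varying residual confounding are observationally
equivalent in this design).

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning (per chain, per imputation, per
pipeline stage); fixed seeds give byte-identical outputs. Ties in PMM donor
selection are broken by the seeded donor draw; reference levels for
smoking/education are never-smoker and less-than-high-school. Degenerate
inputs fail loudly with the offending field named: zero informative strata,
all-missing columns, inverted CIs, flat priors without data.

## Problem sizes used by the acceptance script

Worked examples are exact and instantaneous. The Monte-Carlo blocks use 500
strata per study; 20 seeds for parameter recovery; 10 seeds for the MI bias
check (m = 5); 4000 iterations for prior-only sampling; and 10 seeds per arm
of the selection demonstration. These sizes give standard errors comfortably
inside the tolerances asserted by the test suite.

## Known limitations

- The frailty is a single normal random intercept; real susceptibility may
  be multimodal, which would strengthen (possibly reverse the sign of) the
  selection trend relative to this mechanism.
- The Bayesian sampler is random-walk Metropolis; for many more covariates a
  gradient-based sampler would mix better.
- Imputation assumes MAR given the predictor sets; MNAR sensitivity models
  are not implemented.
- `>1` case per stratum, time-varying exposures, and propensity or
  nearest-neighbour matching are out of scope by design.
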