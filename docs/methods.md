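# Methods

## The screening model

For one adverse-event outcome and one unordered triplet of drug
ingredient–unit combinations, each member of a matched 1:1 case–control
pair carries a ternary dose code per drug, X ∈ {0, 1, 2} (none / low /
high).  The within-pair log odds of being the case is modelled as

    logit P(case) = α + β₁X₁ + β₂X₂ + β₃X₃
                    + β₄X₁X₂ + β₅X₁X₃ + β₆X₂X₃ + β₇X₁X₂X₃

with α a pair-specific nuisance intercept.  Conditioning on one case per
pair removes α exactly: with case design row u and control design row v,
the pair's conditional likelihood is exp(β·u)/(exp(β·u)+exp(β·v)), a
no-intercept logistic likelihood on the within-pair difference u − v
with the outcome fixed at 1.  Concordant pairs (u = v) contribute a
constant log ½ and carry no information about β.  We treat the exact
conditional likelihood as the model's definition; a genuine
random-intercept (mixed-model) fit would integrate over α instead and is
deliberately out of scope — for 1:1 strata the conditional fit is the
standard estimator and is unbiased under stratum heterogeneity of any
form.

The log odds ratio of a dose configuration x = (x₁,x₂,x₃) relative to
(0,0,0) is the design row of x dotted with β; at the highest dose it is
2β₁+2β₂+2β₃+4β₄+4β₅+4β₆+8β₇.  Every dose-reduction test is the Wald
z-test of a design-row difference, so the odds-ratio grid and the
contrast estimates are algebraically consistent by construction (tested
to 1e-12).

## Pipeline

1. **Cohort.** Cases are a person's earliest emergency-department visit
   carrying an outcome diagnosis code in position 1 or 2, with > 365
   days of prior enrollment, no other ED visit in the preceding 180
   days, a 2008–2021 index window, and no outcome diagnosis at any
   earlier time.  Controls satisfy the same visit rules without the
   outcome code.  Matching is greedy 1:1 without replacement: exact on
   gender, race and the binary risk-factor vector; calipers of ±2 years
   on age and ±2 calendar months on index month; cases processed in
   ascending index-date order with ties broken by person id, each taking
   the candidate minimising (|Δage|, |Δmonth|, person id).  Greedy
   nearest-match-without-replacement is the conventional claims-study
   default and is deterministic; optimal matching would recover slightly
   more pairs at substantially more code and is a non-goal.  Age is
   floor((index − Jan 1 of birth year)/365.25) because claims carry
   birth year only; the month caliper compares calendar months, ignoring
   the day.  Risk factors use all available pre-index history (no
   lookback bound).  Unmatched cases are reported in a separate file,
   never silently dropped.

2. **Exposure.** The average daily dose (ADS) of a drug ingredient–unit
   over the 30 days before the index date is
   Σ(dose-per-unit × quantity) / Σ(days supply) pooled over in-window
   fills — for a single fill this is the familiar dose×quantity/days;
   the pooled form is robust to overlapping fills.  A fill dated exactly
   30 days before the index is in-window; the index date itself is not.
   In-window fills with non-positive days supply are rejected with a
   logged count.  The per-drug threshold is the sample median ADS among
   *exposed cases only* (mean of the two middle order statistics for
   even counts, so thresholds are bit-reproducible).  Exposed-only is
   the adopted reading because a zero-inflated median could be 0, which
   would make the low-dose level empty.  Codes: 0 iff ADS = 0, 1 iff
   0 < ADS ≤ median, 2 iff ADS > median.  The dose matrix covers the
   top-K drug-units by exposed-case count (ties lexicographic; K = 200
   by default, scaled down in the demo).

3. **Screen.** Candidate triplets must be co-exposed (all codes > 0) in
   at least `min_case_count` cases (default 500) and intersect a
   required outcome-related drug set (an empty set is a configuration
   error).  Each fitted triplet yields eight one-sided p-values: H0
   βⱼ ≤ 0 for j = 1..7 and the composite highest-dose test.  All eight
   p-values of all tested triplets are pooled into a single
   Benjamini–Hochberg family (a per-test-type family is available but
   off by default).  Signals require (a) composite q < FDR level
   (default 0.05), (b) OR at (2,2,2) ≥ 1.3, and (c) an effect pattern:
   each drug has a positive main-effect estimate or belongs to an
   interaction with q < FDR level.  Criterion (c) is the literal reading
   of "three risky individual drug effects and/or significant
   interaction effects"; it is config-toggleable and every non-signal
   records machine-readable reason codes so alternative readings can be
   audited.  Whether the ≥ 1.3 floor applies only to the highest-dose OR
   or to all 26 exposed configurations is ambiguous; the default applies
   it to OR(2,2,2), with `strict_or_all_configs` covering the stricter
   reading.  Unconverged or separated fits are quarantined and excluded
   from the BH family, with counts in the manifest.

4. **Profile.** For each signal the full 27-configuration odds-ratio
   grid is computed (the complete grid makes figure-style outputs and
   audits trivial even though typical reports show a subset), along with
   ten z-tests against (2,2,2): dose reduction for one drug (221, 212,
   122), two drugs (211, 121, 112), three drugs (111), and
   discontinuation of one drug (220, 202, 022).  Risk reduction is
   significant at one-sided p < 0.05.  Median-OR summaries pool the
   stratum's configurations across signals (each profile contributes
   three values to the one-drug-lower stratum); a per-signal aggregation
   is available behind a flag.

## Estimation and numerics

Newton–Raphson with step-halving from β = 0, gradient-infinity-norm
tolerance 1e-8, at most 100 iterations.  The conditional likelihood is
concave, so the deterministic optimizer is bit-stable; step-halving only
guards pathological curvature.  The covariance is the inverse observed
information at the optimum.  All-concordant designs raise a fit error;
rank-deficient discordant designs raise an error naming the aliased
columns (detected by SVD of the difference matrix).  Any |β̂| > 15
(odds ratio above e¹⁵) flags separation: such fits are quarantined
rather than penalised — Firth-type fallback is noted as an extension
point.  Wald contrasts with zero standard error (e.g. the zero vector)
raise a degenerate-contrast error; the reference configuration (0,0,0)
returns log OR 0 with SE 0 exactly.

## Synthetic data

Two generators, all randomness flowing from one integer seed through
`numpy.random.SeedSequence` with deterministic child streams.

**Matched-pair generator.**  Both members' dose codes are drawn i.i.d.
per drug (default level probabilities 0.5/0.25/0.25 — half of members
unexposed, exposed members split evenly low/high, mirroring the
median-split coding) and the case is assigned by the exact within-pair
conditional probability.  This is the distribution the estimator
assumes, so it supports clean recovery, coverage and calibration
experiments: the test suite verifies that 95% Wald CI coverage at
n = 5000 pairs matches nominal within simulation error for every
coefficient, and that the one-sided composite test's type-I error is
within a percentage point of 5%.

**Population generator.**  Persons carry gender, race, birth year
(1940–1975), enrollment intervals starting 2008–2011 and lasting 4–8
years, and one index ED visit at least 366 days into enrollment.  Drug
exposure is Bernoulli per drug with lognormal ADS; dispensings decompose
the ADS exactly into (dose-per-unit, quantity, days-of-supply) fills
with days ∈ {7, 14, 30} and one or two in-window fills, plus
out-of-window and post-index noise fills that the window logic must
ignore.  The outcome follows a person-level logistic model on dose codes
(coded against each drug's theoretical lognormal median) with planted
triplet effects, per-drug nuisance main effects, and an optional normal
random intercept shared within a coarse matching cell (`stratum_sd`),
which injects the stratum heterogeneity the conditional fit must remove.
Small configurable fractions of persons receive a prior ED visit within
180 days or a prior outcome diagnosis, so the exclusion rules are
exercised on every run.

What the generator does *not* emulate — and hence what passing tests do
not establish about real claims data: real ICD/NDC coding systems,
longitudinal disease progression, time-varying exposure within the
window, correlated co-prescribing (drug exposures are independent given
the planted model), unmeasured confounding beyond the stratum intercept,
and outcome misclassification.  Because the pipeline recodes doses
against case-median thresholds while the generator plants effects on
theoretical-median codes, planted log odds ratios are recovered with
slight attenuation; detection checks use planted effects large enough
that this is immaterial.

**Demo conditions** (bundled `demo_config.yaml`, chosen once): 12 000
persons, 8 drug-units, planted triplet (drug00, drug01, drug02) with
β = (0.4, 0.4, 0.4, 0.05, 0.05, 0.05, 0.04) — highest-dose log OR 3.32 —
exposure probability 0.45 for the planted drugs and 0.3 otherwise,
baseline outcome prevalence 0.12, stratum SD 0.5, `min_case_count` 40
and `top_k` 8 (the frequency and top-K policies scaled to desk size).
A run matches ≈3100 pairs and tests 21 triplets in a few seconds.

## Verification problem sizes

The statistical acceptance tests run at: CI coverage — 1000 replicates
of 5000 pairs; null-screen FDR — 500 screens × 50 triplets × 300 pairs
per triplet (a realistic per-triplet stratum size for a desk-scale
screen); composite type-I error — 3000 replicates of 5000 pairs (Monte
Carlo SE ≈ 0.4 percentage points against a ±1 point band); demo
recovery — 20 seeded end-to-end runs.  The coverage comparison uses a
Šidák-adjusted simultaneous band for the seven correlated coefficients
so the joint Monte-Carlo check keeps a two-SE error rate.  Oracle
equivalence uses a 30–40-pair instance against a zoomed brute-force grid
search of the conditional likelihood (independent implementation) and
against the differenced no-intercept logistic fit from statsmodels;
statsmodels is never on the estimation path.

## Known limitations

- Greedy matching is order-dependent by design (deterministic, but not
  maximum-cardinality); heavily saturated candidate pools can leave
  matchable cases unmatched.
- Triplet enumeration is O(required × viable²) with a frequency prune;
  fine for hundreds of drug-units, not tuned for thousands.
- No defined-daily-dose or morphine-equivalent standardisation: doses
  are compared only within an ingredient–unit combination.
- Separated triplets are excluded rather than penalised, which can
  discard genuinely extreme signals in small strata.
- The effect-pattern signal criterion is one defensible reading of an
  under-specified rule; audits should consult the recorded reason codes.
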