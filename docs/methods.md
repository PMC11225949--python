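# Methods

## The norming model

`cwitnorms` implements regression-based continuous norming for the four
D-KEFS Color-Word Interference Test (CWIT) subtests (color naming, word
reading, inhibition, inhibition/switching), whose outcome is completion
time in seconds over 50 items.

Raw completion times are positively skewed, so norming proceeds in two
stages.

**Stage 1 — percentile-rank normalization.** Raw times are converted to
performance percentiles by midpoint rank: for a raw value `v` with `f`
ties and `c` strictly slower observations in a sample of `N`,

    percentile(v) = 100 · (c + f/2) / N ,

so faster completion earns a higher percentile. Percentiles map onto the
scaled-score metric (mean 10, SD 3, range 1–19) through the standard
normal quantile:

    scaled = clip( round_half_away( 10 + 3·Φ⁻¹(p/100) ), 1, 19 ).

Half-away rounding reproduces every printed percentile anchor of the
published conversion tables (50 → 10, 84 → 13, 99 → 17, 0.4 → 2,
99.6 → 18, …). The resulting raw → scaled assignment is frozen as a
`ConversionTable` of contiguous integer-second bins with open extremes,
so individuals can be scored without the training sample. Raw times are
treated as integer seconds, matching the published tables' bounds. The
exact percentile convention behind the published tables is not printed;
the midpoint rule is the classical-test-theory convention and is
validated only against the printed bins.

**Stage 2 — demographic regression.** Scaled scores are regressed on
age, education (both mean-centered, default constants 46.2 years and
15.5 years), and sex (0 = male, 1 = female). The full model is

    age + age² + age³ + female + edu + edu² + edu³
        + age·female + edu·female + age·edu

and is simplified backwards: at each step every droppable term
(marginality respected — no interaction outlives a dropped main effect,
no power outlives a dropped higher power) is scored by the nested F-test
of its single-term removal; among supported candidates (p ≥ α = .01,
simplification accepted at equality) the lowest-order one is dropped,
ties broken by largest p. BIC is recorded at every step but never
overrides the F decision. The drop order (interactions → cubics →
quadratics → mains) is this package's reading of a hierarchy-respecting
backward search; only the endpoint structure is externally verifiable.

An individual's normed score is then

    Z = (obtained scaled − predicted scaled) / SD_residual ,
    T = 10·Z + 50 ,

with `SD_residual` the final model's residual standard deviation.
Display rounding follows clinical convention — predicted score and Z to
two decimals, T to the nearest integer, halves away from zero — while
full precision is carried internally (the integer T is rounded from the
unrounded chain: 45.93 → 46).

The published Norwegian equations and conversion tables (n = 1011
healthy adults, ages 20–85) ship as a versioned transcription
(`norwegian_norms()`). Scoring outside ages 20–85 warns rather than
fails: the calculator is a clinical aid and the range is advisory. One
published table cell is ambiguous: the word-reading age² coefficient is
printed only as "<−0.001" with CI [−0.002, <−0.001]; the packaged value
is −0.001, the printed precision. With coefficients at printed precision
the oldest published example (age 80, centered age 33.8) reproduces only
to ±2 T because rounding of the age² coefficient is amplified
quadratically; the younger examples reproduce exactly.

## Equality of coefficients across subtests

Whether age ages one subtest faster than another is tested by estimating
both equations jointly as seemingly unrelated regressions — one-step
FGLS: per-equation OLS residuals estimate the 2×2 cross-equation
residual covariance (denominator n), and the stacked system is
re-estimated by GLS. The Z statistic for a shared term is

    z = (b₁ − b₂) / √( var(b₁) + var(b₂) − 2·cov(b₁, b₂) ) ,

two-sided, α = .01. Whether the original analysis iterated the FGLS step
is unstated; one-step estimation is used. A tiny ridge keeps the GLS
step well-posed when the two responses are identical (self-comparison).

## Error norms

Errors are recorded on the inhibition subtests only, as total
(corrected + uncorrected) counts. They are zero-inflated, over-dispersed,
and at most weakly related to demographics, so error norms are
unstratified cumulative percentages: `cumulative(k)` = % of the sample
with ≥ k errors. Blanks at unobserved counts mean nobody sat at exactly
that count, not a zero cumulative. The demographic screen uses Spearman
rho (age, education), Mann-Whitney with the rank-biserial correlation
1 − 2U/(n₁n₂) (sex; tie-corrected normal approximation, no continuity
correction — samples here are large and the original analysis does not
specify), and Pearson r with completion time (Fisher-z CI). The
extreme-group contrast compares completion times between participants
with zero errors on both subtests and those with ≥ 4 on either, by
Welch's t with Satterthwaite df.

## Auditing a norm set

Well-adjusted norms leave no demographic signal: T-scores are regressed
on mean-centered age, education, and sex, and any coefficient with
p < .05 flags a maladjustment. Two norm sets on the same people are
compared by paired t (Cohen's d = mean difference / SD of differences).
The low-score rate (strict T < 35, 1.5 SD below the mean) is tested
against the theoretical normal base rate 100·Φ(−1.5) ≈ 6.7% with a
one-proportion Z-test (no continuity correction, for symmetry with the
uncorrected McNemar below) and a 99% Wilson score interval — the
interval construction is not named in the source analysis; Wilson is
chosen for its behavior near small proportions and isolated behind
`wilson_ci` for easy substitution. Between two norm sets the discordant
low-score flags are tested with the asymptotic McNemar statistic
(b − c)²/(b + c), 1 df, no continuity correction; with no discordant
pairs the statistic is undefined and p = 1 is reported with a note.

## Stability and reliable change

Test–retest pairs with intervals beyond 5 years are excluded, then
ICC(A,1) — single rating, absolute agreement, two-way model — is
computed on normed T-scores (a raw-time option exists):

    ICC = (MSR − MSE) / ( MSR + (k−1)·MSE + (k/n)(MSC − MSE) ),  k = 2,

with the F-based 95% CI of McGraw & Wong (the cited ICC taxonomy does
not fix a CI construction). Absolute agreement makes the coefficient
sensitive to a systematic shift between occasions. Point estimates are
classified by the conventional bands (< .5 poor, .5–.75 moderate,
.75–.9 good, ≥ .9 excellent). Three Reliable Change Index variants are
exposed — with SEM = SD_baseline·√(1 − r₁₂) and SEdiff = √2·SEM:

    Jacobson–Truax:     (follow − base) / SEdiff
    practice-adjusted:  (follow − base − mean_practice) / SEdiff
    regression-based:   (follow − (slope·base + intercept)) / SEE

— together with the materials table (means, SDs, r₁₂, regression of
follow-up on baseline) needed to compute them from published statistics;
|statistic| > 1.96 marks reliable change. The three methods coincide
when the practice effect is zero and the regression is the identity with
SEE = SEdiff (tested as an algebraic identity).

## The synthetic cohort generator

The normative data are restricted ("available on request"), so the test
battery runs on synthetic cohorts that encode the published study
conditions as defaults:

- **Age**: a 50/50 mixture of truncated normals on [20, 85], centers
  29.51 and 68.10, SDs 3.90 and 17.86 — solved once so the mixture
  reproduces the published mean 46.2 and SD 19.4 exactly while mimicking
  the sample's thin middle-age band. The true age distribution's shape
  is not published; the mixture is an artifact convention.
- **Education**: discrete truncated normal on [7, 23], mean 15.5,
  SD 2.9. **Sex**: Bernoulli(.668 female).
- **Times**: latent scaled score = equation prediction + N(0,
  SD_residual); integer scaled = clip(round(latent), 1, 19); raw time
  uniform over that score's conversion bin (geometric tail, p = .5,
  beyond open extremes). Inverting the published table rather than
  fitting a parametric time distribution guarantees that re-scoring a
  generated raw time recovers its generating scaled score exactly — the
  property downstream tests need. The within-bin distribution is not
  published; uniform is the convention here. Where a table cannot
  represent a scaled score (the word-reading table has no raw range at
  17 or 19), the score snaps to the nearest representable value, ties
  toward the scale middle.
- **Errors**: a hurdle model per subtest — the probability of making any
  error equals the published cumulative percentage at k = 1 exactly
  (.514 / .554), and positive counts follow a zero-truncated negative
  binomial fitted once by least squares to the published cumulative
  marginals (all k ≤ 6 within 0.17 pp). A zero-inflated NB was tried
  first and degenerated to a plain NB whose k = 2 marginal missed by
  0.8 pp — too close to the ±1 pp calibration band — hence the hurdle
  form. Errors are independent of demographics by construction.
- **Retest**: follow-up latent scores correlate with the baseline
  residual at a level slightly inflated for rounding attenuation
  (factor (σ² + 1/12)/σ²), so the ICC observed on discretized T-scores
  hits the target (defaults .68/.68/.76/.70 per subtest). Intervals are
  truncated-normal, mean 3.4, SD 0.9 on [1, 5] years, with an optional
  fraction beyond 5 years to exercise the exclusion filter. The mean
  practice effect defaults to 0 scaled points (baseline and follow-up
  means were near-identical in the source sample).

What the generator does **not** emulate: heavy-tailed slow outliers
beyond the conversion tables' open bins, demographically structured
errors, attrition or cognitive decline at follow-up, and measurement
features like examiner effects. Passing tests therefore certify the
statistical machinery under the published effect structure, not
robustness to real-data pathologies.

## Numerical choices and problem sizes

Degenerate inputs are explicit errors: constant raw-time distributions
(percentiles undefined), rank-deficient designs (offending columns
named), zero between-subject variance (ICC undefined), empty extreme
groups (threshold too extreme for the sample). Perfect fits return zero
influence measures rather than 0/0 noise. Stochastic tests are seeded;
whole-cohort generation is a deterministic function of a single spec
seed via spawned seed sequences.

Simulation-based verification uses the sizes the checks are stated at:
coefficient recovery on 100 cohorts of n = 10,000 (pooled per-coefficient
±2 SE coverage ≥ 90%), term-set selection on 100 cohorts of n = 5,000
(exact-set rate ≥ 90% across seed × subtest runs), ICC CI coverage on
100 retest samples of n = 335, score self-consistency and error
calibration at n = 100,000. The full suite runs in about three minutes
on one CPU.

## Known limitations

- The published regression, audit, and stability tables cannot be
  reproduced from raw data (the cohort is restricted); they are verified
  by parameter-recovery simulation instead.
- The packaged equations carry printed precision only; T-scores for
  individuals far from the centering means can differ by up to 2 points
  from full-precision scoring (see the 80-year-old example above).
- External (D-KEFS manual) T-scores are consumed as input only; the
  manual's lookup tables are never re-derived.
- Stepwise selection paths other than the endpoint are unverifiable
  against the source; a different droppable-term ordering could traverse
  different intermediate models.
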