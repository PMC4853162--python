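# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `ambientgxe`.

## Exposure-assessment model

Ambient exposure is modelled from point-located commercial application
events on a planar landscape in metre coordinates. For a subject address
(residential or occupational, per calendar year) and a pesticide, the
annual value is the sum of `pounds/acres` over all applications of that
pesticide in that year within a closed disc of radius `radius_m`
(default 500 m, boundary inclusive, Euclidean distance — no geodesy, since
the landscapes are synthetic and need no datum). The study-window average
runs from `start_year` (default 1974) to `index_year − lag_years`
(default lag 10), both endpoints inclusive.

Years whose address could not be geocoded are imputed with the mean of the
subject's *recorded in-window* years for that (pesticide, setting); a
subject with zero recorded years in the window has undefined exposure and
is excluded from association fits (counted in the run manifest). Because
every missing year receives the recorded mean, the imputed window average
equals the plain mean of the recorded in-window annual sums. The
vectorised engine uses that identity; the record-level operations
(`annual_buffer_sum`, `impute_missing_years`, `window_average`) implement
the sequence literally, and the test suite pins the two paths together
exactly.

Dichotomisation: for each (pesticide, setting), the threshold is the
sample median of window averages among *exposed* controls — controls with
a strictly positive value; zero-exposure controls would otherwise collapse
the median. A subject is "high" when at or above the threshold (inclusive)
and strictly positive. The median of an even-sized sample is the midpoint
of the two central order statistics. Class-level categories count high
pesticides per chemical class, combined across settings (`either` by
default: high at residence or workplace; `both`, `residential_only`,
`occupational_only` available): pyrethroids are `none` vs `any`
(one-or-more), organophosphates and dithiocarbamates are split at the
median count among controls with at least one high pesticide, and paraquat
(a single agent) follows its own label. A configuration switch
(`count_rule: any_nonzero`) counts any positive contact instead of
at-or-above-median contact, since either reading of "number of pesticides
exposed to" is defensible; the median reading is the default.

Simplifications relative to a full GIS treatment: applications are points,
not parcels, so the buffer test is point-in-circle rather than an
area-weighted land-use intersection; there is no crop weighting. The
downstream statistics are invariant to this substitution.

## Genetics

The locus is a biallelic A/G SNP with G fixed as the risk/effect allele.
Codings: additive (0/1/2 copies of G), recessive (GG vs rest), and the
homozygote contrast (AA = 0, GG = 1, heterozygotes excluded). The
Hardy–Weinberg check in controls uses the plain Pearson χ² with 1 df and
no continuity correction; an exact conditional test (enumeration of the
heterozygote count given allele counts, summing configurations no more
probable than the observed one) is provided as the robustness companion.
On the published control counts (175/227/95) the two give p = 0.165 and
p = 0.168 respectively, both consistent with the reported P = 0.18; which
variant produced the published value is ambiguous, so neither is forced to
match it beyond the [0.16, 0.19] band.

## Association models

Logistic models are fitted by Newton–Raphson/IRLS with step-halving.
Convergence requires relative log-likelihood change < 1e-10 and maximum
score component < 1e-8, within 100 iterations; any coefficient exceeding
15 in absolute value triggers a separation error (at that magnitude the
odds ratio exceeds 3×10⁶, the practical signature of complete or
quasi-complete separation), and a rank-deficient design a collinearity
error. The covariance is the inverse observed information; Wald 95%
intervals use the normal 1.96 multiplier (not t), standard for logistic
models at these sample sizes. statsmodels is used in the test suite as an
independent cross-check of coefficients and standard errors, never as the
fitter.

The interaction model is `logit P = β0 + βg·G + βe·E + βge·G·E +
covariates` with age continuous and untransformed, and male sex and
ever-smoking as indicators. Cell odds ratios against the unexposed
reference homozygote are coefficient combinations (e.g.
`exp(βe + 2βg + 2βge)` for exposed GG under additive coding). The
interaction p-value defaults to the Wald test on βge, with the
likelihood-ratio p reported alongside; the two agree within a factor of
1.5 for small effects at n ≥ 1000 (checked). Subjects with missing
genotype, undefined exposure, or missing covariates are dropped listwise
with counts kept on the Results object and in the run manifest, and an
empty or genotype-constant exposure stratum raises an inestimability error
naming the cell. Demographic comparisons use the pooled-variance two-sided
t-test (continuous) and Pearson χ² without continuity correction
(categorical). The eQTL statistic is the tie-corrected Spearman rank
correlation between allele count and expression with the t-approximation
p-value (scipy), plus an optional permutation p (exhaustive at n ≤ 8).

## Synthetic cohort generator

The generator emulates a retrospective case-control design on a
10 km × 10 km landscape. Defaults are the study conditions: 465 cases and
497 controls, risk-allele frequency 0.42 (the control-genotype
distribution), index years 1998–2007, address histories from 1974 with a
10% per-(subject, year, setting) independent missing-geocode rate, and 60%
of subjects holding a geocoded workplace address. Application intensities
are homogeneous Poisson processes per chemical class; the pyrethroid rate
(3.4 events/year over the region) was calibrated once so that the exposed
fraction of controls matches the ~28% of the published stratified table,
and then frozen. Pounds and acres are lognormal with medians of roughly
33 lb and 16 acres per event. Addresses do not move within a setting — a
simplification the exposure engine does not rely on (it accepts arbitrary
per-year addresses).

Disease status follows
`logit P(case) = β0 + βg·G + βe·E + βge·G·E + βage·(age−65) + βsex·male +
βsmoke·smoker` with G the allele count and E the true binary class
exposure. Default effects mirror the motivating study's pattern: null
genotype and exposure main effects, a positive per-allele interaction
(βge = ln 1.65, putting the doubly-exposed-GG joint OR near 2.7), slight
male excess and smoker deficit among cases. The intercept is set to a
source-population prevalence of 25% rather than a realistic rare-disease
value: under outcome-dependent (case-control) sampling every odds ratio is
invariant to β0, and the oversized-source approach (default 3× the target
cohort) would otherwise need tens of thousands of subjects per replicate.
Exactly `n_cases` cases and `n_controls` controls are sampled without
replacement; optional frequency matching of controls to the case
age-decade distribution is off by default, as the matching protocol is not
part of the modelled design.

True exposure must be defined the way the analysis defines it —
thresholds from exposed *controls* — but control status itself depends on
exposure. The generator resolves the circularity with a two-pass draw
under common random numbers: pass 1 computes exposure with
whole-population thresholds and draws provisional outcomes; pass 2
re-thresholds on the pass-1 non-cases and redraws outcomes from the same
uniforms. The remaining gap between generation and analysis is then pure
sampling noise in the control medians, which attenuates the recovered
interaction coefficient by a few percent (visible in the recovery numbers
below, and the reason a one-pass design was rejected: population
thresholds differ *systematically* from control thresholds whenever
βge > 0, roughly doubling the attenuation).

Randomness is organised as one RNG stream per stage (applications,
genotypes, addresses, covariates, outcomes, sampling, power), each derived
from the master seed by a fixed label, so outputs are bit-for-bit
reproducible and a change to one stage's parameters leaves other stages'
draws untouched.

What the generator does *not* emulate: residential mobility, spatially
clustered agriculture and land use, correlated missingness (e.g. whole
address spells failing to geocode), genotyping error, exposure
measurement error beyond geocoding gaps, and confounding between exposure
and covariates. Passing calibration tests on this generator therefore
demonstrates the correctness and calibration of the *statistical
machinery* under the design's assumptions, not robustness of the design to
those real-data features.

## Power and calibration

Power is estimated by full-pipeline simulation: each replicate redraws the
source population, samples the cohort, re-assesses exposure with
sampled-control thresholds, and fits the interaction model. The
application landscape is generated once per power run and reused across
replicates — it is the fixed environment; replicates vary the people.
Replicates failing with separation or inestimability are counted and
reported; more than 20% failures raises an unstable-design error. The
rejection fraction carries an exact Clopper–Pearson interval.

Problem sizes used by the shipped checks (chosen to make Monte-Carlo error
small relative to the bands being tested): null calibration uses 2000
study-sized replicates (the 95% band around a true 5% rate is then about
±1%); coefficient recovery uses 200 replicates of 2500 + 2500 with
βge = ln 2.5; the acceptance script scales the null run to 500 replicates
and adds a 500-replicate power estimate at the default effect size.
Observed behaviour at these sizes: null rejection ≈ 0.048, mean recovered
βge ≈ 0.88 vs truth 0.916 (the threshold-noise attenuation noted above),
CI coverage ≈ 0.92, and power ≈ 0.57 at the study size against the
default βge = ln 1.65.

## Known limitations

- Point-source exposure with no parcel geometry or land-use weighting.
- No Firth correction or exact logistic regression, so genuinely sparse
  cells fail (loudly) rather than being shrunk.
- No conditional/matched logistic model; frequency matching in the
  generator is approximate (age decades).
- Single biallelic locus; no haplotypes, no multi-SNP models.
- The exact HWE test enumerates all heterozygote configurations; it is
  intended for cohort-scale samples, not biobank-scale ones.
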