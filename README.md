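# ambientgxe

Gene–environment interaction analysis for case-control studies with
GIS-style ambient pesticide exposure assessment — plus a synthetic cohort
generator and simulation-based power, so the entire pipeline is testable
without any restricted individual-level data.

The package is aimed at genetic epidemiologists studying how a common
variant (here modelled on *HLA-DRA* rs3129882, alleles A/G with G the risk
allele) modifies the effect of ambient pesticide exposure — pyrethroids,
organophosphates, dithiocarbamates, paraquat — on disease risk in a
retrospective case-control design such as a population-based Parkinson's
disease study.

## The model

**Exposure assessment.** Every commercial application event has a point
location, year, pesticide, pounds applied and acres treated. A subject's
annual exposure to a pesticide at an address is

```
E_year = Σ (pounds_i / acres_i)   over applications of that pesticide,
                                  that year, within 500 m of the address
```

averaged over the study window `[1974, index_year − 10]` (index year =
diagnosis for cases, interview for controls). Years with no geocoded
address are imputed with the subject's mean over recorded years. Each
pesticide is dichotomised at the median window average among *exposed*
controls (at-or-above = high); class-level exposure counts high pesticides
per chemical class: one-or-more for pyrethroids, at/above the exposed-
control median count for organophosphates and dithiocarbamates, the single
agent's label for paraquat.

**Association.** With `G` the risk-allele count (additive coding, or the
AA-vs-GG homozygote contrast) and `E` the binary class-level category, the
interaction model is

```
logit P(case) = β0 + βg·G + βe·E + βge·G·E + βage·age + βsex + βsmoke
```

fitted by iteratively reweighted least squares. Results report the
genotype × exposure odds-ratio table against the unexposed-AA reference —
joint cells are coefficient sums, e.g. `exp(βe + 2βg + 2βge)` for exposed
GG — with the multiplicative-interaction p-value from the Wald test on βge
(likelihood-ratio p alongside). Marginal genotype effects, Hardy–Weinberg
χ² and exact tests, demographic t/χ² comparisons, and a Spearman rank eQTL
statistic round out the analysis.

## Worked example

```python
from ambientgxe import SimConfig, ExposureConfig, generate_applications, \
    generate_cohort, compute_exposure, gxe_analysis
from ambientgxe.exposure import class_exposure_vector

sim = SimConfig()                        # 465 cases / 497 controls, seed 0
apps = generate_applications(sim)
cohort = generate_cohort(sim, apps, ExposureConfig())
expo = compute_exposure(apps, cohort.addresses, cohort.subjects)
res = gxe_analysis(cohort.subjects,
                   class_exposure_vector(expo, "pyrethroid"),
                   model="additive",
                   chemical_class="pyrethroid")
print(res.summary())
```

prints (abridged):

```
Gene-environment interaction model (additive)
  chemical class: pyrethroid
  n analysed: 962 (of 962)

 exposure genotype  n_cases  n_controls    OR  ci_low  ci_high     p
     none       AA       91         126 1.000     NaN      NaN   NaN
     none       AG      142         172 1.171   0.929    1.476 0.181
     none       GG       53          52 1.371   0.863    2.179 0.181
  exposed       AA       51          52 1.240   0.804    1.912 0.330
  exposed       AG       83          70 1.735   1.239    2.429 0.001
  exposed       GG       45          25 2.427   1.499    3.932 0.000

  interaction OR per risk allele: 1.195 (0.811, 1.761)
  interaction p (Wald): 0.3688
  interaction p (LRT):  0.368
```

The cohort was generated with a per-allele interaction log-odds of ln 1.65
and null main effects: the doubly-exposed GG cell shows an elevated joint
odds ratio (2.43, CI 1.50–3.93) while neither factor alone reaches it —
the signature pattern of a multiplicative interaction. This particular
realisation's interaction *test* is non-significant (p ≈ 0.37): at 962
subjects the test's power against this effect size is only ≈ 0.57 (see the
power numbers the acceptance script computes), a deliberately realistic
feature of study-sized cohorts.

The same models run from the shell:

```
ambient-gxe run-all --seed 7 --out out/
ambient-gxe power --replicates 500 --out power.csv
```

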