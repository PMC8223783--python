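# Methods

## Problem and scope

The package links two observations: (1) vitamin A deficiency (VAD)
prevalence among women of childbearing age differs strongly between
ethnic groups, and (2) the population frequencies of variants associated
with low serum retinol differ between ancestry groups in a way that is
unusually large compared to random SNPs. The analysis chain is:
stratified prevalence with exact two-group comparisons; a SNP-panel
allele-frequency dispersion statistic with a permutation null drawn from a
genome-wide background; and a two-locus risk-genotype classification with
Hardy–Weinberg expectations. Survey-design weighting (strata/PSU/design
variance) is deliberately out of scope: the stratified proportions are
unweighted count ratios, which is also what the packaged published tables
contain. A `weight` column is accepted by the cohort schema but only a
plainly-labelled weighted proportion would use it; no design-based
variance is offered.

## Deficiency classification and prevalence

A record is deficient when serum retinol < 1.05 µmol/L (strict: 1.05
itself is sufficient) and severely deficient below 0.70 µmol/L. The WHO
supplementation trigger is ≥ 20% of pregnant women below the severe
cutoff. Cohort inclusion keeps ages 17–42 inclusive and requires
retinol, poverty-income ratio (PIR) and ethnicity to be present; records
failing a rule are counted per reason in an exclusion log, and no
imputation is attempted. The poverty band is strict PIR < 1.85, so a
boundary record (PIR = 1.85) falls in the non-poverty band.

Prevalence CIs default to the Wilson score interval, which behaves well at
the small stratum sizes involved (8–44 in the Bronx strata);
Clopper–Pearson and the normal approximation are selectable and the method
name is carried in every estimate. Two-group comparisons default to
Fisher's exact test with two-sidedness by the point-probability rule (sum
the probabilities of all tables no more probable than the observed one)
and to the conditional-MLE odds ratio with its exact interval — the
convention pair under which the published interval 0.04–0.22 is an exact
odds-ratio CI. A chi-square two-proportion alternative is provided; where
the published record is ambiguous about which test produced which p-value,
no attempt is made to force both. For 2×k categorical covariates the
exact conditional test is computed by full enumeration of tables with the
observed margins (up to total n = 500; chi-square beyond), which
reproduces the published 2×3 ethnicity association p = 0.311.

## Dispersion statistic and permutation test

Per SNP, the statistic is the standard deviation of the tabulated allele's
frequency across the K groups; per panel, the unweighted mean over member
SNPs. Choices that the published description leaves open, all recorded in
the result object and switchable:

- SD divisor: sample (K−1), the common statistical-software default;
  population (K) available.
- p-value: r/B where r counts null statistics ≥ observed (ties toward the
  tail, conservative) — under this convention a reported p = 0.030 with
  B = 1000 is exactly attainable as 30/1000; the add-one convention
  (r+1)/(B+1) is always reported alongside.
- Null sampling: each iteration draws m distinct SNPs uniformly without
  replacement from the background; iterations are independent. No
  MAF-matching of random sets is applied by default (an option exists
  because panel/background frequency imbalance is a known confounder in
  SNP-set testing — not enabled unless asked for).
- When the panel's SNP ids occur in the background table, they are excluded
  from the permutation pool by default (logged). For calibration
  experiments where the panel is itself a random subset of the background,
  exclusion should be turned off: keeping the panel in the pool makes the
  observed statistic and the null draws exactly exchangeable, so the
  p-value is uniform on its attainable grid. With exclusion and a small
  background, the null is narrowed by the finite-population correction
  (factor ≈ 1 − (m−1)/(n−1)) and the test is slightly anti-conservative;
  with a genome-scale background the distinction is negligible.

The grouping (which populations, how many) is a runtime property of the
input table; simulated tables default to K = 5 labelled ancestry groups.

## Generative models

Balding–Nichols frequencies: ancestral frequency p uniform on
[0.05, 0.95] (configurable; avoids degenerate fixed SNPs), group
frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so mean p and across-group
variance F·p(1−p). The background and the trait panel differ only in F;
the default panel F = 0.3 vs background 0.05 emulates a strongly
ancestry-differentiated trait architecture and is the condition under
which the test's power is measured.

Genotypes: Hardy–Weinberg at each locus, loci independent (rs10882272 is
on chromosome 10, rs738409 on 22; no linkage disequilibrium model).
Genotypes are unordered and phase-free; "CT" and "T/C" normalise to "TC".
The "higher risk" rule is exactly "risk-homozygous at ≥ 1 locus";
heterozygote-dose scores are deliberately not invented. The observed
TOPMed carrier percentages and the HWE expectations computed from PAGE/ALFA
frequencies come from different data sources, so the package reports both
modes side by side (`source` column) and does not adjudicate between them.

Cohort retinol is log-normal. The per-allele effect enters as
log(1 − 0.03) per rs10882272 C copy, making the published 3.0% mean
decrement exact on the mean ratio (risk homozygote / non-carrier =
0.97² ≈ 0.941); multiplicative effects are the standard model for
concentrations. Published data give no retinol distribution beyond group
means and SDs, so log-normality is a modelling convention, not an
empirical claim. Defaults, chosen once to resemble the survey strata the
cohort emulates: three groups (non-Hispanic Black, Mexican American,
Asian) with published risk-allele frequencies (rs10882272 C: 0.617,
0.260, 0.106; rs738409 G: 0.144, 0.50, 0.44); baseline log-retinol 0.33,
0.42, 0.46 with σ_log = 0.25, placing unconditional deficiency fractions
in the low-percent to low-teens range; pregnancy assigned at rate 0.25
(the pregnant fraction of the emulated survey strata) with a
multiplicative retinol shift of 0.8; PIR ~ Gamma(shape 2, scale 1)
(mean 2.0, SD 1.4, matching the printed PIR means/SDs); ages uniform on
17–42. Pregnancy and PIR effects are configurable shifts, not fitted
models.

What the generator does **not** emulate: linkage disequilibrium, survey
design (clustering, oversampling, weights), assay noise or detection
limits in retinol, age trends, and any correlation between PIR and
retinol. Passing tests therefore validate the statistical machinery under
a clean generative model, not robustness to those real-data features.

## Verification design and problem sizes

The published genome-scale result (panel mean SD 0.122, p = 0.030 against
1000 random 39-SNP draws from 6,025,429 SNPs) depends on an external SNP
list and genome-wide background that are inputs, not package constants;
the permutation machinery is therefore validated by its operating
characteristics under the generative model, at sizes chosen to keep the
full suite fast:

- type-I error at α = 0.05 over 1000 replicates (background 500 SNPs,
  m = 39, B = 200, panel kept in the pool — see above);
- power at panel F = 0.3 vs background 0.05, K = 5, m = 39, B = 1000,
  over 100 replicates (background 2000 SNPs);
- exact agreement in mean and variance with full C(n, m) subset
  enumeration on small backgrounds;
- allele-complement invariance of the statistic and p-value;
- uniformity of the empirical p under exchangeability against the exact
  discrete CDF (k+1)/(B+1).

Permutation seeds are kept independent of data-generation seeds
(different streams) so the null sampling never shares randomness with the
background it samples from. Deterministic spot-checks (the published
prevalences, both exact tests, the ALFA dispersion 0.244, the HWE
arithmetic) are asserted at printed precision against brute-force oracles
written independently of the implementation path (hypergeometric
enumeration for Fisher's test, direct arithmetic for SDs).

## Numerical and degenerate-input conventions

Frequencies are validated to [0, 1] at every ingestion point with
line-numbered errors; duplicate SNP ids are rejected; a panel id missing
from its table is an error listing the ids. A zero margin in a 2×2
comparison yields p = 1 with an undefined odds ratio and a degeneracy
flag rather than an exception. Empty strata and empty groups are omitted
with log entries. Constant covariates are skipped. The 3×3 expected
combination table sums to 1 exactly (it is an outer product of exact
per-locus vectors); observed proportion tables sum to 1 up to float
rounding. All generators are bit-reproducible under a fixed seed.

## Known limitations

- The exact 2×k enumeration is exponential in k and capped at small
  totals; beyond the cap the chi-square approximation is used silently
  (recorded in the result's `test` field).
- The weighted-proportion path carries no design-based variance; treating
  survey data as simple random samples understates uncertainty.
- VCF ingestion requires biallelic records and user-declared INFO keys;
  no liftover or allele harmonisation beyond complement-invariance of the
  downstream statistic.
- The dispersion statistic is the plain cross-group SD by design; it is
  not an FST estimator and is not corrected for sample size per group
  (group sample sizes are typically not published alongside frequency
  tables). The dispersion function is pluggable for users who want a
  different per-SNP measure.
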