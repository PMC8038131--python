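# Methods

This note documents the models, defaults and design choices behind
`gmdrprs`, and what the synthetic-data experiments do and do not show.

## Pipeline overview

1. **Per-SNP screen** (`gmdrprs.screen`): QC (call rate, MAF,
   Hardy–Weinberg) and covariate-adjusted logistic association per SNP;
   candidates pass `p < p_threshold`, `MAF > maf_min`, `HWE p > hwe_min`.
2. **LD pruning** (`gmdrprs.ld`): EM haplotype frequencies, |D′|,
   greedy same-chromosome pruning at |D′| ≥ 0.4.
3. **GMDR search** (`gmdrprs.gmdr`): exhaustive k-subset evaluation by
   10-fold cross-validated balanced accuracy, sign test and CVC.
4. **PRS** (`gmdrprs.prs`): risk-allele orientation, unweighted allele
   counting, tertile banding, category odds ratios.
5. **PRS × exposure interaction** (`gmdrprs.gxe`) and **diet patterns**
   (`gmdrprs.diet`).

The three genuinely fit/transform-shaped stages are exposed as
scikit-learn estimators (`GMDRSearch`, `PolygenicRiskScorer`,
`DietPatternAnalyzer`) so they compose with sklearn pipelines and model
selection; simulation, file I/O, the per-SNP screen and LD pruning are
plain functions, and the module-level functions elsewhere are thin
wrappers over the estimators.

## Statistical models and conventions

**Genotype coding.** Additive minor-allele counts 0/1/2 everywhere;
`NaN` is missing. Risk-allele orientation happens only in the PRS
stage, because the risk allele may be the major allele (a minor-allele
OR below 1).

**HWE test.** One-df chi-squared against expectations from the sample
allele frequency; an exact test (conditional enumeration of
heterozygote counts) is available and recommended below MAF 0.05.
Monomorphic SNPs get p = 1 with a warning. The test is invariant to
swapping the allele labels.

**Association fits.** statsmodels maximum-likelihood logistic (Newton /
IRLS, tolerance 1e-10, ≤ 100 iterations); Wald 95% CIs
`exp(β ± 1.96·SE)` and Wald p-values, matching the reporting style of
candidate-SNP tables (a likelihood-ratio variant exists for the
interaction test). Separation is declared at |β| > 15 or
non-convergence and reported as a flagged, non-estimable effect rather
than a huge finite OR. The screen's default thresholds (p < 1e-6,
MAF > 0.01, HWE p > 0.05) are configuration, not constants: published
candidate tables are not always consistent with their stated
genome-wide threshold, so the pipeline never hard-codes it.

**Two-locus EM.** For biallelic loci only the double-heterozygote cell
is phase-ambiguous; EM splits it between AB/ab and Ab/aB in proportion
to `f_AB·f_ab / (f_AB·f_ab + f_Ab·f_aB)`, iterated until no frequency
moves more than 1e-10 (≤ 200 iterations). The EM margins equal the
observed allele frequencies exactly, which the tests assert. |D′| is
reported with the sign discarded (Haploview convention):
`D = f_AB − f_A·f_B`, `D′ = |D| / D_max` with
`D_max = min(f_A f_b, f_a f_B)` for D > 0, else
`min(f_A f_B, f_a f_b)`.

**Pruning rule.** Within each chromosome, candidates are visited most
significant first and dropped on first conflict at |D′| ≥ threshold
(default 0.4) with an already-kept SNP; every removal is logged with
its partner and |D′|. The source literature does not state which SNP
of a high-LD pair is dropped; keep-most-significant is this package's
choice and makes the result order-independent for distinct p-values.
Cross-chromosome pairs are never tested.

**GMDR.** Scores are response residuals from the covariate-only
logistic null model; with an intercept they sum to zero. Cell rule:
high iff the training score sum exceeds T = 0; ties and empty training
cells are low (a test-time "exclude subject" policy is available).
Balanced accuracy is computed against true case/control labels, which
makes the engine reduce exactly to classic MDR under 1:1 sampling with
no covariates — the suite checks this equivalence against a
from-scratch oracle on all instances with ≤ 3 SNPs and ≤ 60 subjects.
Folds are stratified by outcome and keyed to subject id + seed, so row
order cannot change results. The sign test is the exact
`Binomial(n_folds, ½)` upper tail of the number of folds with test BA
\> 0.5; the printed 10-fold values 0.0010 / 0.0107 / 0.0547 / 0.1719 /
0.3770 for 10/9/8/7/6 wins are reproduced to 4 decimals. CVC counts
folds whose training-best subset equals the overall best (best = max
mean TEBA; ties broken by higher CVC, then lexicographic order).
Exhaustive enumeration is the default and is intended for ≤ ~15
candidates; a greedy `forward` strategy reproduces nested
"model k plus one SNP" sequences. A note on a visible but harmless
artifact: when the cell partition is identical in every fold and the
class counts divide evenly by the fold count, mean TRBA equals mean
TEBA algebraically.

**PRS.** Pure allele counting, no β-weighting (a weighted variant
exists behind a flag, off by default). Tertile band presets are the
published cutpoints (5 SNPs: 0–3 / 4–5 / ≥6; 6 SNPs: 0–3 / 4–6 / ≥7)
rather than re-derived tertiles, because a reference cohort's score
distribution is not reproducible; empirical tertiles are available.
Subjects missing any model SNP are excluded by default (mean imputation
is opt-in and logged in the profile). Orientation rejects OR = 1
exactly — there is no direction to orient by.

**Interaction models.** Exposures are dichotomized with "high"
including the cutoff value (published footnotes define the reference
side as `< cutoff`); percentile cutoffs (diet patterns at the 70th) are
computed on the full analysis sample. The interaction is tested by a
likelihood-ratio test of PRS × exposure product terms over the
main-effects model, with the PRS as an ordered 0/1/2 category score
(1 df) by default and a categorical 2-df option — the source df is
unstated, and the 1-df trend test is the more powerful default for a
monotone score. When the tested exposure also appears in the covariate
list it is dropped from the adjustment set for that exposure's models;
a rank check rejects any remaining collinearity explicitly. Sparse or
separated strata are reported as non-estimable, never silently dropped.

**Diet patterns.** Principal-component extraction on the correlation
matrix (the retention rule in the source methodology is stated in PCA
terms), retain eigenvalue > 1.5, normalized-Kaiser varimax rotation to
1e-8. Rotation preserves per-variable communalities, asserted to 1e-8.
Factor signs are fixed so each factor's largest-|loading| variable
loads positively. Scoring uses the regression method `F = Z R⁻¹ Λ`;
for PCA loadings this gives scores with zero mean, unit variance and
exact zero correlation on the fitting sample. Loadings with |value| ≥
0.40 are flagged as each pattern's significant contributors.

## Synthetic-cohort generator

The generator emulates the statistical structure of a large
hospital-based Korean cohort study at desk scale:

- **Genotypes**: HWE sampling per SNP from its MAF; the default
  10-SNP panel carries the published chromosomes, positions, alleles
  and MAFs (0.020–0.378). LD blocks are drawn as haplotype pairs whose
  frequencies realize a requested |D′| (minor alleles positively
  associated); the default is full independence.
- **Outcome**: Bernoulli from an additive-logistic model; default
  per-SNP ORs are the published 0.76–1.94 values, and the intercept is
  calibrated by bisection (tolerance 1e-4 in prevalence, ≤ 50
  iterations) to the study's prevalence 495/56,934 ≈ 0.9%. Epistasis
  is encoded as log-odds increments on specific two-locus genotype
  cells, not product terms, because cell-pattern effects are what
  MDR-type methods detect — this keeps the recovery experiments
  well-posed.
- **Exposures**: marginals loosely matched to the study's summary
  tables (WBC ~ N(5.7, 1.5)·10⁹/L truncated > 0 with cutoff 4; energy
  ~ N(96, 25) % of estimated requirement, cutoff 100; alcohol
  log-normal with cutoff 20 g/day; seaweed log-normal with cutoff
  2.65 g/day; age, gender, BMI, residence, education, income). Only
  these marginals are published, so joint dependence between exposures
  is not modeled. An opt-in flag makes exposures depend on the outcome
  (mean shift for cases) to emulate post-diagnosis behaviour change;
  it is off by default so null-calibration experiments are honest.
- **Food groups**: 29 columns with four latent diet-pattern factors
  (traditional-balanced / prudent / noodle-meat / rice-based blocks,
  loading 0.75); groups outside the blocks are noise. The mapping of
  patterns to factors in tests is by generator block labels, not by
  name.

All randomness flows from one explicit seed through
`numpy.random.SeedSequence` spawning; no global state.

**What passing tests show — and don't.** The generator's SNPs are
independent (except requested blocks), its exposures are conditionally
independent given outcome, and its effects are exactly logistic.
Recovery and calibration results therefore demonstrate correctness of
the machinery, not robustness to population stratification, genotyping
batch effects, correlated diet measurement error or case–control
ascertainment bias, none of which are simulated. Cohort-specific
published effect sizes (e.g. a high-vs-low PRS OR near 3.9) depend on
the inaccessible real data and are deliberately not simulation targets;
the package instead checks parameter recovery against planted truths
and analytic values.

## Experiment sizes and numerical choices

Chosen so the full suite runs comfortably on one CPU:

- Epistatic-pair recovery: 50 replicates (20 in the acceptance
  script), n = 5,000, 10 candidate SNPs, MAF 0.3, +1.0 log-odds on all
  cells where both causal loci carry ≥ 1 minor allele, balanced
  case–control sampling (prevalence 0.5). Recovery ≥ 90% required;
  observed 100% across seeds.
- EM recovery: n = 10,000 from haplotypes (0.4, 0.1, 0.1, 0.4),
  tolerance 0.01; D′ vs the direct formula at 1e-12 over a 196-point
  frequency grid.
- Null calibration: HWE at n = 300 over 1,000 fixed seeds (rejection
  rate asserted in [3%, 7%] at α = 0.05); interaction LR p over 500
  simulations at n = 1,000 tested for uniformity by Kolmogorov–Smirnov
  at α = 0.01.
- PRS calibration: per-allele log-OR 0.2 on six MAF-0.3 SNPs,
  intercept −2. Analytic category ORs come from exact enumeration of
  the score distribution (convolution of six HWE genotype
  distributions) collapsed within bands; Wald-CI coverage is asserted
  over 100 replicates × 2 contrasts against the binomial acceptance
  band for 0.95.

Degenerate inputs are errors, not silent coercions: monomorphic SNPs
in HWE/D′ warn and return the defined value (p = 1, D′ = 0); folds
missing a class, empty PRS reference bands, constant exposures,
rank-deficient designs and unresolvable prevalence targets all raise
with actionable messages.

## Known limitations

- Exhaustive search cost grows as C(m, k); the engine is meant for the
  post-pruning candidate scale (≤ ~15 SNPs), not genome-wide data.
- The EM is two-locus only; no multi-locus phasing or haplotype blocks.
- No population-structure correction (genomic control, PCs) in the
  screen; the generator does not simulate stratification either.
- Logistic fits use Wald inference by default; profile-likelihood CIs
  are not implemented (the LR test is available for interactions).
- The published tertile band presets exist only for 5- and 6-SNP
  models; other sizes must use empirical tertiles or explicit bounds.
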