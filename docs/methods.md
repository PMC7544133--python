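# Methods

This note documents the statistical models the package implements, the
assumptions behind them, the synthetic-data generator that stands in for the
real study inputs, and the numerical and design choices that were genuinely
open.

## Two-sample MR model

The package treats a set of independent biallelic variants as instruments for
a standardized quantitative exposure (height, per SD) against a binary outcome
(atrial fibrillation, log-odds scale). Per-variant exposure effects β̂_X ±
se_X come from one GWAS, outcome effects β̂_Y ± se_Y from another;
harmonization aligns both to the exposure's effect allele before estimation.
The identifying assumptions are the usual three: relevance (instruments
associated with the exposure — monitored by per-variant F), independence
(no confounding of the variant–outcome association), and exclusion (effects
on the outcome run only through the exposure — probed rather than assumed,
via Egger's intercept, the weighted median, and MR-PRESSO).

Estimators and conventions:

* **IVW**: ratio-weighted meta-analysis with second-order-free weights
  (β̂_X/se_Y)². Default standard error is multiplicative random effects —
  the fixed-effects SE inflated by max(1, √(Q/(k−1))) — because large
  polygenic instruments are overdispersed in practice. The weighting variant
  is recorded in the estimate's metadata.
* **MR-Egger**: weighted least squares of β̂_Y on β̂_X with an intercept,
  variants oriented so β̂_X ≥ 0. SEs carry a multiplicative overdispersion
  factor max(1, √(RSS/(k−2))); p-values use t(k−2). Egger is reliable only
  when instrument strength varies and no near-null instruments are present;
  see the generator calibration below.
* **Weighted median**: linear interpolation of the weighted empirical CDF of
  the per-variant ratios at 0.5, convention p_j = (cumsum(w) − w/2)/Σw. The
  SE is a parametric bootstrap (default 1,000 resamples, seeded).
* **MR-PRESSO**: leave-one-out IVW residual sum of squares compared with its
  distribution under n_sim parametric simulations of the fitted
  no-pleiotropy model (default 5,000, seeded); per-variant outlier tests are
  Bonferroni-corrected; the distortion test compares the observed shift of
  the outlier-corrected estimate against the shift from removing random
  subsets of the same size. Empirical p-values are bounded below by
  1/(n_sim+1).
* **Multivariable MR**: no-intercept WLS of β̂_Y on the matrix of exposure
  effects with weights 1/se_Y²; rank deficiency raises an error naming the
  collinear exposures.
* 95% CIs always use β ± 1.959964·se on the log-odds scale; odds ratios are
  produced only at the reporting boundary. `scale_per_unit` multiplies β, se
  and the CI bounds by target/SD (e.g. per-SD → per-10cm with SD 9.28 cm).

Instrument strength uses R² = 2·MAF·(1−MAF)·β² (MAF folded from the effect
allele frequency; β assumed on the per-SD exposure scale, with the exposure's
trait SD available as a rescaling flag) and F = R²(N−2)/(1−R²). Sample-overlap
bias uses the first-order approximation bias = overlap × confounded
observational effect / mean F; the confounded effect defaults to 0.2 SD and
the type-I-error projection evaluates the shifted normal test at a supplied
IVW SE (default 0.05).

## Harmonization and clumping

Allele pairs are matched directly or on the opposite strand; reversed pairs
get β negated and eaf complemented. Palindromic variants (A/T, C/G) are
resolved by allele-frequency agreement when both frequencies lie outside
[0.42, 0.58], and dropped otherwise; each variant carries an action label
(unchanged / flipped / inferred_palindromic / dropped_palindromic). Indels and
multi-allelic records are rejected at read time — the instrument is SNP-only.

Clumping is greedy: visit variants by ascending p (ties broken by chrom, pos,
id for determinism); each retained index variant discards all variants on the
same chromosome within ±window (inclusive, default 10,000 kb) with r² above
threshold (default 0.001). Variants absent from the LD panel are treated as
unlinked with a logged warning rather than silently dropped. The test suite
verifies the greedy output exhaustively against the clump definition on small
random instances and checks row-order invariance.

## Individual-level model

The GRS is Σ dosage·weight, standardized within the cohort (population SD).
Two-stage MR: stage 1 is OLS of height on the GRS, age, sex, genetic PCs
(default 6, following a scree rule implemented as the smallest k whose
cumulative variance share reaches 0.7) and the model's clinical covariates,
fitted on outcome-free individuals only; stage 2 is logistic regression of
the outcome on stage-1 predictions for all individuals with the same
covariates and HC1 sandwich SEs. Both stages adjust for the identical
covariate list. Per-SD scaling uses the whole-cohort height SD. The nested
models are: base (age, sex, PCs), a clinical model adding weight and twelve
comorbidity indicators, and an echocardiographic model adding left atrial
diameter on the complete-case subset (excluded-row counts are reported).
Covariates that are constant on the analysis rows (e.g. sex within a
sex-stratified run) are dropped with a log entry rather than crashing the
design matrix.

Demographics tables report mean (SD) with Wilcoxon rank-sum p for continuous
characteristics and n (%) within stratum with Fisher's exact p for binary
ones; percentages print with one decimal below 3% and as integers otherwise.

## PheWAS

Codes map to phecodes; an individual is a case at ≥ 2 code occurrences
(configurable), excluded from controls when carrying any code in the
phecode's exclusion range or when of the non-applicable sex for flagged
phenotypes, and a control otherwise. Each phenotype with ≥ 20 cases is tested
by logistic regression on the standardized predictor with age, age², sex and
10 PCs; non-convergent fits are skipped with a diagnostic, never silently
reported. The significance threshold is α divided by the number of phenotypes
actually tested.

## The synthetic-data generator

`SimConfig` fixes the full generative model: k independent variants with
maf ~ U(0.05, 0.5) in Hardy–Weinberg equilibrium; per-variant effect
magnitudes drawn shifted-exponential (0.5 + Exp(0.5), random sign) and scaled
so the instrument explains a configured share of the exposure variance
(default 11.2%). The magnitude distribution is deliberately bounded away from
zero: an instrument made of genome-wide-significant hits contains no
near-null effects, and its per-variant strength is right-skewed with the
minimum a few-fold below the mean. Near-null instrument effects would also
break Egger's orientation step in ways the real instrument cannot.

The exposure is standardized-liability: height = Σ g·β + γ_X·U + ε with a
latent confounder U; the outcome is Bernoulli with logit = α + θ·height +
Σ g·α_pleio + γ_Y·U + age and sex terms, α solved numerically for the target
prevalence. Directional pleiotropy is drawn per exposure-increasing allele
(N(mean, sd), default mean 0.02) and mapped to the effect allele, so
"directional" remains directional after orientation; balanced pleiotropy sets
the mean to zero; a configurable fraction of variants is affected. Optional
outcome-only variants (zero exposure effect, direct log-odds ≈ ±0.3) supply
the reverse-direction instrument for bidirectional MR. The outcome GWAS is
drawn under case-control ascertainment (cases oversampled to the configured
counts); exposure/outcome sample overlap is controlled as the fraction of the
outcome sample drawn from the exposure sample. The biobank-style cohort
shares the same variant effects and adds clinical covariates, independent
standard-normal PCs (no population structure), and a height- and
outcome-associated left atrial diameter with ~57% missingness.

Defaults form the desk-scale preset: 200 variants, exposure GWAS of 20,000,
outcome GWAS of 2,000 cases / 8,000 controls, cohort of 6,000 at ~30%
prevalence. Everything is bit-identically reproducible from (config, seed).

Two generation modes exist. The individual-level mode draws genotypes and
runs true per-variant marginal regressions (vectorized closed-form linear and
batched-Newton logistic scans). The summary-level mode draws effect estimates
directly from the sampling distribution the same model implies
(β̂_X ~ N(β_X, se_X) with se_X = 1/√(2p(1−p)·n); analogously for the logistic
outcome with the case-fraction variance factor, and correlated errors under
overlap). The summary-level mode makes hundreds of replicates cheap; the test
suite cross-checks its SE scale against the individual-level scan.

What the generator does **not** emulate: LD structure (variants are
exchangeable and independent; the LD panel is still computed and exercised,
but clumping removes nothing by construction), population stratification,
assortative mating, and EHR-style measurement error in covariates. Passing
tests therefore demonstrate estimator correctness under the stated model, not
robustness to those real-data features.

## Calibration of the validation grids

Two sample-size regimes appear in the validation suite, chosen to preserve
the relevant properties of the study rather than its raw sample counts:

* **Estimator-recovery grids** (IVW bias/coverage, Egger intercept) run the
  summary-level mode with the exposure n set to ≈ 200,000 so mean F ≈ 110 at
  200 variants and 11.2% variance explained. Two-sample IVW carries a
  regression-dilution bias of order θ/F̄; it is instrument strength, not n
  itself, that governs estimator behavior, and the study's instrument has
  mean F ≈ 110. At a literal n = 20,000 the same heritability would give
  F̄ ≈ 11 and a dilution bias no estimator can avoid.
* **End-to-end runs that include the significance-selection step**
  (threshold → clump → harmonize → estimate) use fewer, stronger variants
  (e.g. 80 variants explaining 45%) so that variants genuinely clear
  p < 5×10⁻⁸ at n = 20,000. Even so, selection at reduced n induces a mild
  winner's curse — selected exposure effects are slightly overestimated, so
  ratio estimates attenuate a few percent, visible in the README example.
  The real study mitigates this with n ≈ 700,000.
* The **weighted-median contamination cell** (40% invalid instruments) uses
  25 strong instruments and the study-scale outcome GWAS. The weighted
  median's intrinsic displacement under one-sided 40% contamination is about
  z₀.₈₃ × (per-variant ratio noise), so demonstrating its robustness bound
  requires instruments whose ratio noise is small; 25 instruments is the
  standard design in the robust-MR literature.
* The **two-stage recovery** tolerance (|mean log-OR − planted| < 0.05 over
  100 cohorts of 6,000) budgets Monte-Carlo error plus the small logistic
  non-collapsibility attenuation that arises because the residual height
  variance unexplained by the GRS acts as an omitted covariate (≈ 2% on the
  log-OR at OR 1.75 with R² ≈ 0.11).

## Numerical choices and degenerate inputs

Empirical p-values never return 0 (lower bound 1/(n_sim+1)). Monomorphic
variants in a GWAS scan are emitted with β = 0 and infinite SE, flagged, and
excluded downstream by harmonization's finiteness requirement. A zero-variance
GRS raises at standardization rather than propagating NaNs. Logistic
separation in stage 2 or a PheWAS fit raises (or skips, for PheWAS) with a
diagnostic. Summary-statistics files round-trip bit-identically (17
significant digits on write, round-trip float parsing on read). Clumping ties
on p are broken by (chrom, pos, variant_id). All stochastic operations
(weighted-median bootstrap, MR-PRESSO simulations, the generator) take
explicit seeds.

## Known limitations

Correlated instruments are out of scope (no generalized IVW); mode-based and
contamination-mixture estimators are not implemented. The overlap-bias
formula is a first-order approximation, not a simulation. The phecode map is
user-supplied; no proprietary code tables ship with the package. LD panels
are either user pair lists or dosage correlations; no remote reference
panels, liftover, or imputation.
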