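# Methods

## The problem and the design

Genome-wide scans for gene–environment (here gene–sex) interactions are
underpowered relative to main-effect scans: with balanced binary factors the
interaction coefficient's asymptotic variance is four times the main
effect's, so a standard case–control interaction analysis needs roughly a
4-fold larger sample for the same power. The package implements the
two-step design that mitigates this: a **case-only screen** followed by
**case–control validation**.

Among cases, regressing the factor (sex, coded female = 1) on allele dosage

    logit P(female | case) = a0 + a1 * dosage + covariates

gives `a1` as an estimate of the SNP×sex interaction log-odds-ratio for
disease, *provided* genotype and sex are independent in the source
population and the disease is rare. The case-only test is considerably more
efficient than the full interaction model, but its validity collapses when
gene–factor independence fails (e.g. sex-differential allele frequencies);
hence step 2, the standard model on cases and controls pooled:

    logit P(D) = b0 + b1*SNP + b2*sex + b3*SNP*sex + covariates

whose `b3` is robust to that dependence. Covariate adjustment throughout is
smoking status (ever/never) plus five principal components, with study
indicators wherever studies are pooled.

### The cascade

Per SNP, in order:

1. **Imputation-quality filter.** Info score ≥ 0.7 in the discovery study
   (inclusive), > 0.2 in *each* replication study (strict), and
   sample-size-weighted replication info ≥ 0.7 (inclusive).
2. **Case-only screen.** Discovery cases and pooled replication cases
   (study indicators as covariates) are tested separately and combined by
   inverse-variance fixed-effect meta-analysis. Heterogeneity is summarised
   by Cochran's Q and I² = max(0, (Q−(k−1))/Q)·100.
3. **Step-1 call.** Joint P below the configured threshold *and* strictly
   more significant than both arms. (The latter clause can be disabled via
   `ScanConfig.require_joint_more_significant` for threshold-saturation
   plumbing checks.)
4. **Case–control validation** on all cases and controls pooled, interaction
   P < 0.05.
5. **Firth confirmation** when the pooled minor-allele frequency is below
   0.05, at the same 0.05 level. Low-frequency variants put few carriers in
   the interaction cell, where ordinary maximum likelihood is biased away
   from zero and may not preserve type-I error; the Jeffreys-prior penalty
   ½·log det I(β) removes the O(n⁻¹) bias and keeps estimates finite even
   under separation.

Every SNP yields a complete `ScanRecord`; stage failures are recorded on
the record and the scan continues. Records are ordered by (chrom, pos) and
the whole scan is deterministic given its inputs.

The genome-wide default `joint_p_threshold = 5e-8` presumes ~10⁷ tests at
consortium sample sizes. A desk-scale run on a handful of synthetic SNPs at
a fraction of those n should use a Bonferroni level matched to what is
actually scanned; the acceptance tests use 0.01 for 3-SNP scans at 1/5-scale
cohorts, where the planted signal's expected joint z is ≈ 4.

### Inference conventions

All single-coefficient inference is Wald: z = β/SE against the standard
normal, two-sided; OR = exp(β). This holds for the Firth fit too (the
penalized-likelihood-ratio test would be an alternative with slightly
better small-sample behaviour; Wald was chosen for uniformity with the scan
and with the meta-analysis back-reconstruction). Back-reconstruction of a
standard error from a printed (OR, P) pair inverts the same identity:
SE = |ln OR| / Φ⁻¹(1−P/2), which is what allows published per-study rows to
be re-combined; printed 2–3 significant figures propagate into ~1% relative
error on a reconstructed joint OR.

Logistic fits use Newton/IRLS with step-halving; convergence when the
largest (modified) score falls below 1e−6 or the step below 1e−8, at most
50 iterations. Ordinary estimates wandering past |β| = 30 are declared
separated (no plausible log-OR lives there) and the error message points to
the Firth fit. Covariance is the inverse observed (penalized) information.
Complete-case analysis per SNP: rows with missing dosage or covariates are
dropped for that SNP only. Minor-allele orientation is fixed per variant
from the pooled frequency so one MAF describes all studies.

The genomic-control factor is λ = median(χ²₁-quantiles of the p-values) /
0.4549; ≈1 indicates calibrated tests.

## The synthetic-cohort generator

`SimScenario` → `simulate_collection` emulates the structure the analysis
assumes, not any particular dataset:

* Genotypes are Hardy–Weinberg draws at per-SNP MAFs from `maf_range`;
  `maf_sex_delta` (female − male allele frequency) plants the
  gene–sex dependence that breaks the case-only test — the sexually
  antagonistic selection scenario. Autosomes only; no LD haplotypes.
* Disease follows the logistic model with additive dosage, sex, smoking,
  PC and SNP×sex terms; case–control ascertainment is rejection sampling
  from a base population (adaptively chunked, capped at ~50× the nominal
  requirement; an unattainable target raises `SimulationError`).
* Imputation is emulated as the posterior mean E[g | g + ε], ε ~ N(0,
  `info_noise_sd`), under the HWE prior — which is what imputation software
  outputs (a shrunken dosage), unlike raw additive noise, which would
  *inflate* dosage variance. The per-SNP info score is the variance ratio
  Var(dosage)/Var(genotype) capped at 1: exactly 1 for noiseless dosages
  and monotonically decreasing in the noise. (The common 2p(1−p)
  denominator convention is not used because finite-sample hard genotypes
  do not satisfy Var(g) = 2p̂(1−p̂) exactly.)
* Defaults mirror large lung-cancer consortium margins: 40% female, smoking
  prevalence 0.87 (men) / 0.73 (women), a mild male excess among cases
  (β_sex = −0.075 for female), smoking log-OR 1.5, baseline prevalence 5%.
  SNP effects default to the global null.
* All randomness descends from one scenario seed through
  `numpy.random.SeedSequence` spawn keys (one stream per study), so a
  (scenario, seed) pair reproduces a collection byte-for-byte.

What passing tests on these cohorts do **not** show: robustness to LD
structure, population stratification beyond Gaussian PCs, X-chromosome
dosage compensation, genotyping batch effects, or real imputation-quality
heterogeneity. The generator is a correctness harness, not a cohort model.

Note the rare-disease caveat when planting effects: the case-only estimand
equals the interaction log-OR only as the outcome becomes rare. Scenarios
meant to recover a planted β3 should keep the baseline prevalence at a few
percent at most; at 10–20% prevalence with strong covariate effects the
estimand is visibly attenuated (this is a property of the design, faithfully
reproduced, not an artifact).

## The expression (eQTL) stage

Dosage → best-guess genotype coding follows the published windows exactly.
Additive (MAF ≥ 0.1): ≤ 0.2 → 0, [0.4, 0.6] → 1, ≥ 0.8 → 2; dominant
(MAF < 0.1): ≤ 0.4 → non-carrier, ≥ 0.6 → carrier. Dosages in the unlisted
gaps are coded missing (conservative best-guess semantics). The windows as
printed are internally awkward — a dosage of exactly 1.0 falls in the
"≥ 0.8 → 2" window — but they are reproduced literally rather than
second-guessed; integer-dosage idempotence therefore holds for {0, 2} under
the additive rule and for all codes under the dominant rule.

Expression processing order is fixed: duplicate samples averaged on the
rpkm scale, then the rpkm < 0.25 filter, then log2. Group comparisons are
equal-variance Student's t (Welch behind a flag); a stratum whose smaller
genotype group has ≤ 1 sample is reported not-estimable rather than raising.
The genotype×sex interaction on log2 expression is OLS
(`log2(rpkm) ~ code + sex + code:sex`) with t-based two-sided p. Region
summaries pair each SNP's risk-interaction z (joint case-only meta) with its
expression-interaction z and the LD r² (squared Pearson correlation of
dosages) against a reference SNP.

## Design-evaluation utilities

`required_n_ratio` evaluates the expected information of the balanced
case–control logistic design **at the null** (all coefficients 0, intercept
at outcome balance, so every cell weight is 1/4). The required-n ratio then
depends only on the design frequencies and equals exactly 4 for two
independent binary factors at frequency ½ — the score-type local
approximation; evaluating at the alternative would move the ratio by O(β²).
The brute-force companion `simulated_variance_ratio` fits both models on
simulated cohorts and returns the empirical estimator-variance ratio, which
is the required-n ratio asymptotically; it replaces a full power-curve
crossing search at a small fraction of the cost.

`run_calibration` is the replicated simulate→test loop behind the type-I,
power and bias claims; `low_maf_bias_study` compares ordinary and Firth
interaction estimates across a MAF grid with batched replicates so paired
|bias| win rates are assertable. The Firth advantage is only resolvable
when the small-sample bias is material relative to Monte-Carlo noise; the
shipped configuration (β3 = ln 4, baseline logit −1, MAF 0.01, n = 3000,
20 × 800 replicates) was sized by a prior bias measurement.

## Problem sizes used by the test suite

Worked examples are instantaneous. The simulation-backed checks use:
calibration and bias demonstrations at 2000 replicates of 400+400-sample
cohorts; parameter recovery at 500 replicates of 800-case cohorts at 1%
prevalence; cascade recovery over 20 seeded replicates of a 9-study,
~11 800-subject collection (1/5 of consortium scale); a 5000-SNP null scan;
and 16 000 replicates for the low-MAF bias comparison. The full suite runs
in under two minutes on one core.

## Known limitations

* Wald inference everywhere; no penalized-likelihood-ratio option yet.
* No LD simulation, X chromosome, or population-structure model.
* The replication arm is pooled with study indicators by default; the
  alternative 9-study meta-combination is available via
  `ScanConfig.replication_mode = "per_study_meta"` but the subtype filter
  only applies to the pooled path.
* VCF support is read-only DS dosages plus a minimal writer for round-trip
  testing; no BGEN/PLINK binary formats.
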