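# Methods

## Statistical model

### Replication-based weighted sums

Genotypes are biallelic SNV minor-allele counts *g* ∈ {0, 1, 2}, oriented so
the counted allele is the minor allele of the combined case-control sample
(ties at frequency exactly 0.5 keep the ALT allele counted; orientation is
idempotent). For one gene and a binary phenotype with *n*₁ cases among *n*
samples, each variant contributes a copy split (*k′*, *k*) — copies in
cases and controls. Writing *m* = *k′* + *k* and *q* = *n*₁/*n*, the weight
of an oriented variant is the negative log one-sided binomial tail

- case excess (*k′* > *k*):  *w* = −ln P(X ≥ *k′*),  X ~ Binomial(*m*, *q*)
- control excess (*k′* < *k*): *w* = −ln P(X ≤ *k′*)

Ties (*k′* = *k*) contribute nothing. The group sums S₊ and S₋ combine into
S_max = max(S₊, S₋), S_comb = S₊ + S₋ and the data-weighted

S_tau = τ·S₊ + (1 − τ)·S₋,  τ = n₊ / (n₊ + n₋),

where n₊/n₋ count the oriented variants per group. S_tau is a convex
combination of S₊ and S₋: it reduces to S₊ when every oriented variant is
case-enriched (τ = 1) and to S_comb/2 in the balanced case (τ = 1/2), so it
adapts between the "one direction dominates" regime that motivates S_max and
the "even mixture" regime that motivates S_comb. The weight function is an
argument of `compute_rbs`; substituting a constant 1 reduces the sums to
plain counts of oriented variants. The binomial-tail weight is this
package's concrete choice for "weight by how surprising the imbalance is";
it rewards extreme splits and is exact at any *m*.

Degenerate gene (no oriented variant, i.e. every variant tied or no variants
after filtering): all statistics are 0, τ is reported as 0.5, the result is
flagged, and the p-value is 1 — no evidence either way.

### Comparators

**Variable-threshold (VT) burden.** For each candidate MAF cutoff *T* the
per-sample burden b(T) sums counts over variants with MAF ≤ *T*; the score is
z(T) = Σ(yᵢ − ȳ)bᵢ / sqrt(Σ(yᵢ − ȳ)²·Var(b)), and the statistic is
max over *T* of z(T). The default candidate set is the distinct empirical
MAFs of the gene's variants, so every variant defines a cutoff. The maximum
is re-taken inside every permutation, which makes the permutation p-value
valid regardless of the standardization details. Burden weights are unit
(configurable by pre-scaling counts); cutoffs whose burden is constant
across samples are skipped, and a gene with no usable cutoff is degenerate
(p = 1).

**C-alpha.** With p₀ = *n*₁/*n*, yᵢ the copies of variant *i* in cases and
nᵢ its total copies, T = Σᵢ[(yᵢ − nᵢp₀)² − nᵢp₀(1 − p₀)]. Each term has null
mean ~0 under the binomial model; overdispersion (a mix of risk and
protective variants) inflates T. The exact binomial null variance, grouped
by distinct nᵢ, feeds a diagnostic z-score only; inference is by
permutation of the upper tail of T, which targets the overdispersion
alternative (T is negative for under-dispersed data). Note the permutation
null mean of T is not exactly 0 but the small finite-population correction
Σᵢ[Var_SRS(yᵢ) − nᵢp₀(1 − p₀)], where Var_SRS is the without-replacement
variance of the case copy sum; the test suite checks the empirical
permutation mean against this exact formula.

**SKAT-style score test.** Q = r′ G W² G′ r, with r = y − ȳ the residuals of
the intercept-only null model, G the count matrix and W the diagonal of
Beta(MAF; 1, 25) densities (the conventional rare-variant up-weighting).
Q is direction-agnostic and invariant to swapping case/control coding.
Inference is by permutation, which is exact at small n; a Satterthwaite
moment-matched chi-square p-value (`skat_asymptotic_pvalue`) is provided as
a large-sample diagnostic. The reference implementation's small-sample
moment adjustment is deliberately not reproduced: permutation already gives
exact-level inference in the small-sample regime this package targets.

## Permutation inference

P-values use the add-one estimator p = (1 + #{permuted ≥ observed})/(B + 1)
with B label permutations preserving the case/control counts; p is never 0,
is bounded below by 1/(B + 1), and is a valid p-value under exchangeability.
Ties are counted with a 1e-9 relative tolerance (counting ties as "≥" is
conservative). All six methods share one permutation stream per gene — this
removes between-method Monte Carlo noise when methods are compared on the
same data, and the data-adaptive pieces (the VT threshold maximization, the
RBS τ) are recomputed within every permutation. Per-gene permutation seeds
derive deterministically from (analysis seed, gene id) via a CRC32 mix, so
results are byte-identical across runs and independent of gene order.
Rejection is one-sided (upper tail) for all six statistics, and the default
protocol applies no multiple-testing correction — per-gene α = 0.05, with a
Bonferroni option off by default.

A distinct null-resampling device, `null_resample_phenotype`, flips each
sample's label independently with probability 0.5. Unlike label permutation
(which conditions on the observed case/control counts), this makes the
phenotype marginally independent of genotype with Binomial(n, 1/2) group
sizes; it is the cohort-level mechanism used to measure type-I error, while
label permutation is the per-test inference engine.

## Synthetic cohorts

The generator emulates a small sequencing study of unrelated individuals:

- **MAF spectrum**: Beta(0.18, 9) truncated to (1/(2·10⁴), 0.05) — heavily
  skewed toward very rare alleles, with the lower truncation representing
  the resolution of a ~10⁴-chromosome reference pool. Configurable.
- **Genotypes**: Binomial(2, maf) per variant — Hardy–Weinberg proportions,
  independent variants (no linkage disequilibrium).
- **Disease model**: P(case) = logistic(β₀ + Σ causal effect × count), with
  per-causal-variant log-odds magnitudes uniform on [0.5, 2.0], all-risk by
  default (`risk_fraction` < 1 produces a risk/protective mix, the regime
  S_tau is designed for) and baseline β₀ = 0.
- **Sampling**: retrospective — individuals are drawn from the population
  model until exact case and control quotas are filled (defaults 55/48,
  a 103-sample cohort), so the analyzed composition is fixed. At 50%
  baseline prevalence and no genetic effect the expected number of draws is
  about twice the cohort size.
- **Architecture ranges**: gene regions of 20–200 rare variants carrying
  0–9 causal ones by default. The generator warns when a drawn architecture's
  signal strength (causal / total rare variants) exceeds 4.5%, the band
  characteristic of realistic gene-scale targets; deliberately stronger
  architectures (as in the power demonstrations) simply carry the warning.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure (a real cohort's neighbouring variants are correlated,
which can transfer signal between genes), population stratification,
genotyping/sequencing error, missingness, relatedness, and covariates.
Passing calibration and power checks on these cohorts therefore demonstrates
the correctness and relative behaviour of the tests under idealized
sampling, not their field performance on structured data.

## Type-I-error and power protocol

`estimate_type1` simulates one cohort, then per replicate (200 by default)
replaces the phenotype with an independent Bernoulli(0.5) flip-resample and
reruns every test — genotypes fixed across replicates, mirroring a real
study where only the null phenotype is resampled (`fresh_genotypes=True`
redraws them). `estimate_power` draws a fresh cohort per replicate. Both
report per-gene × per-method rejection proportions with Monte Carlo
standard errors; `method_average` gives the gene-averaged rate per method.
The canonical calibration design (`null_calibration_study`) uses 10 null
genes, 103 samples, 200 replicates and 999 permutations at α = 0.05: with
add-one permutation p-values, p ≤ 0.05 corresponds to at most 49 of 999
permuted statistics reaching the observed value, an event of probability
exactly 50/1000 under exchangeability with continuous statistics, so the
measured rate sits at the nominal level up to discreteness (ties bias it
slightly conservative) and Monte Carlo noise.

## Numerical and design notes

- MAF is computed on the combined case-control sample; the rare-variant
  filter keeps 0 < MAF < 0.05 (strict on both sides: monomorphic variants
  carry no information, and "less than 5%" is read strictly).
- Missing VCF genotypes are imputed as 0 copies with the per-variant
  missingness rate recorded — conservative for burden-type sums.
  Multiallelic records are skipped, not split.
- Binomial tails are evaluated through `scipy.stats.binom` per distinct
  total copy count, then looked up per (variant, permutation), keeping the
  permutation engine vectorized; tails are bounded below by qᵐ > 0 so the
  log-weights are finite.
- The problem sizes used in the shipped studies (10 genes × 200 replicates
  × 999 permutations; 400 replicates × 499 permutations for the power
  comparison) were chosen so Monte Carlo standard errors are small relative
  to the quantities compared.
- `simulate_phenotype` labels an existing genotype matrix prospectively;
  the retrospective quota loop lives in `simulate_cohort`, which returns
  genotypes and phenotype together (a phenotype that selects a sample
  subset cannot stay aligned to a fixed genotype matrix).

## Known limitations

- No covariate adjustment, quantitative traits, family data or X-chromosome
  handling; no Davies-type exact mixture-of-chi-square inversion for the
  SKAT-style statistic.
- Permutation p-values have resolution 1/(B + 1); genome-wide significance
  levels would require prohibitive B (use the per-gene α protocol or the
  Bonferroni option instead).
- C-alpha is blind to patterns whose terms are permutation-constant (e.g. a
  lone singleton at an exactly balanced design), and all tests lose power
  as variants become so rare they are monomorphic in-sample.
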