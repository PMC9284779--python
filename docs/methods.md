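# Methods

## Scope and shape

The package re-implements, as a tested library plus narrative analysis
drivers, the sub-haplotype fine-mapping chain used for high-LD loci such as
17q21.31: QC → pairwise D′ LD with confidence bounds → Gabriel-style block
construction → EM phasing → block/sub-haplotype case–control association →
two-stage meta-analysis → sub-haplotype quantitative-trait association.
Imputation, phasing against reference panels, RNA-seq quantification,
enrichment analysis and all wet-lab procedures are out of scope; the
post-imputation quality filter is provided generically as a per-variant
score threshold.  There is no shell CLI: the `analysis/` scripts and the
`pipeline.run_stage`/`run_meta` functions are the intended entry points.

## Synthetic cohorts

`pools.build_default_pools()` encodes the three blocks (H1.1: 5 SNPs,
H1.2: 8, H1.3: 9) with their published Stage 1 sub-haplotype allele strings,
frequencies and odds ratios (reference haplotype log-OR 0; ORs from 0.22 to
2.51), positions placed within the published block spans.  H1.3's printed
frequencies sum to 0.99 and are renormalized (relative frequencies
preserved).  The reference haplotype of each pool is the designated "a"
haplotype — the one carrying log-OR 0 — rather than the numerically most
frequent string, because the combined case+control frequencies printed for
H1.1 make the risk haplotype ACTTG (0.27) marginally more common than the
reference ACTCT (0.25).

Blocks are in complete intra-block LD: chromosomes are drawn only from the
pool haplotypes, with no recombination, mutation or inter-block LD (an
optional clade-coupling mode adds an H2-like tag SNP at frequency 0.2 that
overrides chromosomes in every block, supplying the correlation needed for
H1-homozygote stratification).  The disease model is additive on the logit
scale, P(case) = logistic(β₀ + Σ_h β_h d_h) summed over blocks.  The default
β₀ = −4 gives a baseline prevalence near 2%; study-sized cohorts are then
resampled retrospectively to fixed case/control counts (2,780/6,384 and
2,699/2,230).  This mirrors the rare-disease case–control design and keeps
chromosome-level odds ratios essentially equal to exp(β_h); with a common
disease (large β₀) the sample OR would attenuate toward the null even
though the generative model is exactly logistic.

Quantitative traits are linear in dosage: trait = Σ_h e_h d_h + γ′c + ε,
where e_h is the raw-scale per-copy effect (4.7 for the H1.1 protective
haplotype, 5.0 and 2.9 for the elevated H1.2/H1.3 haplotypes, 1.0
otherwise), c are sex/age/PMI/RIN-like covariates and ε is Gaussian
(default sd 1).  Copy-number traits are diploid sums of per-haplotype
integer contributions (gamma region: 2 copies on the elevated haplotypes
versus 1, giving ~4 versus ~2 per genome; a second region with a 3-to-5
gradient) plus Gaussian measurement noise (default sd 0.3).  Genotyping
noise is independent per entry: missingness at a fixed rate and symmetric
single-step genotype errors (0→1, 2→1, 1→0/2), the simplest model that
exercises the call-rate and HWE filters.

What the generator does not emulate — and what passing tests therefore do
not show — includes partial intra-block LD and recombinant haplotypes,
imputation dosage uncertainty, population stratification confounding
(cohorts are single-population; the PCA covariates are exercised only on
explicitly planted two-population scenes), genotyping error that is
correlated within samples or variants, and X-chromosome handling.

## QC

Filters run in a fixed order: variant call rate ≥ 0.98, MAF ≥ 0.01 (boundary
kept), sample call rate ≥ 0.98 (computed after the variant filters, which is
order-dependent), optional IBD screen, Hardy–Weinberg exact test p ≥ 1e-4,
optional imputation-score filter (pass-through with a warning when the
column is absent).  The HWE test is the exact conditional test, two-sided by
heterozygote probability, applied to all samples (the source protocol does
not restrict to controls); thresholds 1e-4/1e-6 for pre/post-imputation use
are both exposed.  Sex checks are skipped deliberately; ancestry-reference
clustering is out of scope, with the PCA limited to producing regression
covariates (variants standardized by mean 2p and sd √(2p(1−p)),
mean-imputed missing entries, top-k left singular vectors scaled by the
singular values, sign fixed by the largest-magnitude loading).

IBD is method-of-moments on IBS counts.  The expected IBS-given-IBD terms
use unbiased estimators of the allele-probability monomials (falling
factorials of the allele counts) rather than plugging in frequencies, which
removes most finite-sample bias; Z estimates are bounded to the simplex
(overshoots snapped to the corresponding corner, negatives zeroed and the
rest rescaled).  Pairs with Z0 ≤ 0.8 are flagged.  No LD pruning precedes
the IBD scan; with tightly linked variants the estimates would be
overconfident, so the pipeline only runs the scan on request.

## LD and blocks

Two-locus haplotype frequencies come from the standard EM in which only the
double heterozygote is ambiguous; marginal allele frequencies are preserved
exactly and the estimate matches a 1D grid maximization of the multinomial
likelihood to 1e-4 (tested).  D′ confidence bounds profile the likelihood
on a 101-point linear grid of D′ ∈ [0, 1] in the direction of the point
estimate, holding allele frequencies at their MLEs, and take the 5th/95th
cumulative percentiles of the normalized profile (90% coverage, the Gabriel
convention).  Pair classification uses strong-LD bounds 0.98/0.70 and a
recombination bound 0.90; pairs whose rarer allele has expected count < 5
are non-informative.  Candidate blocks are contiguous runs (2–15 markers,
≤ 160 kb) with a strong outermost pair and ≥ 95% strong informative pairs,
ranked by physical span and accepted greedily without overlap.  The
original analysis used a closed-source implementation, so the
informative-fraction rule, recombination bound and greedy acceptance follow
the published Gabriel/Haploview conventions and are all configurable;
exact published block boundaries are accordingly not treated as a
reproduction target.

## Phasing

Within a block the haplotype universe is the union over individuals of the
haplotypes compatible with their genotypes (heterozygous sites unresolved,
missing sites summed over), coded as ≤15-bit integers; the EM runs on
unique genotype patterns weighted by multiplicity, which makes cohort-scale
estimation take milliseconds.  Defaults are 50 iterations and tolerance
1e-4 on the largest frequency change, with a logged warning if the cap is
reached; the log-likelihood trace is retained and its monotonicity is
asserted in tests.  If pathological missingness pushes the universe past
10⁵ candidates the EM raises an error rather than attempting a
partition-ligation scheme — blocks are capped at 15 markers, so this can
only arise from data that should not have survived QC.  Haplotypes below
1% frequency are pruned from reporting and association without
renormalizing the remainder (raw scale retained, matching the source
protocol's frequency tables); individuals whose posterior mass is mostly on
pruned haplotypes are logged.  Association regressors are
posterior-expected dosages (rows sum to 2), not best-guess diplotypes;
labels are block id + a, b, c… by descending frequency with lexicographic
tie-breaks.  Block definitions serialize to JSON and can be applied to a
second dataset without re-detection (the two-stage design).

## Association and meta-analysis

The per-block signal is a likelihood-ratio test: all non-reference
haplotype dosages plus covariates versus covariates only, df = number of
non-aliased dosage columns.  At n = 1,000 the empirical type-I error sits
near 0.055 — the mild anticonservatism expected of the asymptotic LRT with
several moderately rare regressors — and within the 0.05 ± 0.014 band
asserted in the calibration test.  Per-haplotype reporting follows the
published tables: chromosome-level counts (dosage sums rounded), sample OR
against the most common haplotype, Woolf CI (Haldane–Anscombe 0.5 on zero
cells, flagged), two-sided Fisher exact p, plus an additive-dosage Wald
test from the logistic model.  Perfect separation and non-convergence are
flagged, never silently returned.  FDR is Benjamini–Hochberg across the
blocks of one run.

Meta-analysis accepts printed summaries (log-OR and SE recovered from an OR
with its 95% CI, se = (ln hi − ln lo)/3.92) or 2×2 counts (Woolf SE, 0.5
correction on zero cells).  Fixed effects are inverse-variance or
Mantel–Haenszel with the Robins–Breslow–Greenland variance; random effects
are DerSimonian–Laird with τ² truncated at zero, so homogeneous inputs
reduce exactly to fixed effects; heterogeneity is Cochran's Q at k−1 df,
computed from inverse-variance weights for summary inputs (count-based Q
can differ in the second decimal).  The DL estimator is cross-checked
against R's metafor in the test suite.  Units present in only one stage are
emitted unpooled with a flag.

## Quantitative traits and dPCR

Traits are residualized by OLS on covariates (complete cases; residuals
orthogonal to the design), standardized per dataset (ddof 1) and
concatenated without re-standardization — the combined vector is
deliberately not re-scaled, so dataset weights are proportional to sample
size.  The joint linear model on non-reference dosages reports each
haplotype's contrast against the reference with two-sided t-tests and the
model R²; aliased columns are dropped with a log entry.  dPCR assays use
the Poisson partition model λ = −ln(1 − positives/total) and copies per
genome = 2·λ_target/λ_reference; saturated targets are an error.

## Problem sizes and numerical choices

Simulation-based checks use the sizes that make their guarantees
meaningful rather than maximal: EM recovery at n = 2,000 individuals over
20 seeds; LD oracle equivalence on 50 small cohorts plus phased-truth
comparison at n = 1,000; block boundary recovery over 100 seeded two-pool
regions at n = 1,000; calibration over 1,000 null replicates at n = 1,000;
planted-OR recovery over 50 seeds at the Stage 1 size (2,780/6,384).  All
randomness flows through numpy Generators seeded explicitly; EM
initialization is the allele-frequency product blended 9:1 with uniform;
likelihood evaluations clip probabilities at 1e-300; frequency-rank label
ties break lexicographically.  Degenerate inputs (monomorphic loci,
all-missing individuals, zero-variance dosages, saturated dPCR wells,
empty strata, all-pruned blocks) raise errors or return flagged/sentinel
results as documented per function.
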