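# hapblock

Sub-haplotype block fine-mapping of a high-LD locus, modelled on the
17q21.31 (*MAPT*/*KANSL1*) region: genotype QC, Gabriel-style haplotype
block detection from D′ confidence bounds, EM haplotype phasing,
case–control and quantitative-trait association against the most common
sub-haplotype, and two-stage fixed/random-effects meta-analysis.  A
synthetic-cohort generator reproduces the locus structure — three blocks of
5/8/9 SNPs in complete intra-block LD, sub-haplotype frequencies from 0.48
down to 0.01, per-haplotype disease odds ratios spanning 0.22–2.51, 3–5-fold
expression elevations on protective haplotypes, and integer-ish copy-number
traits — so the whole pipeline runs end to end with known ground truth and
no external data.

It is written for statistical geneticists who want a transparent, tested
reference implementation of this analysis chain (the original was run in
closed-source software) and for anyone who needs the individual pieces:
a Wigginton-style Hardy–Weinberg exact test, PLINK-style method-of-moments
IBD, two-locus EM with D′ confidence bounds, multi-marker EM phasing with
diplotype posteriors and dosages, DerSimonian–Laird/Mantel–Haenszel
pooling, or Poisson dPCR quantification.

## The model in brief

For a block of *m* ≤ 15 biallelic SNPs, haplotype frequencies **f** are
estimated by EM over the haplotypes compatible with each individual's
unphased genotypes (50 iterations, tolerance 10⁻⁴; haplotypes below 1%
pruned).  Blocks themselves are found from pairwise D′ = |D|/D_max with
likelihood-profile confidence bounds: a pair is in "strong LD" when its
upper bound ≥ 0.98 and lower bound ≥ 0.70, and a block is a contiguous run
(≤ 15 markers, ≤ 160 kb) whose outermost pair is strong and ≥ 95% of whose
informative pairs are strong.  Association uses each individual's expected
haplotype dosage d_h ∈ [0, 2]: per block, a likelihood-ratio test of all
non-reference dosages in an additive logistic model; per haplotype, the
chromosome-count odds ratio against the most common haplotype with a
two-sided Fisher exact p.  Stages are pooled by inverse-variance fixed
effects and DerSimonian–Laird random effects (τ² from Cochran's Q), with
Mantel–Haenszel pooling available for count inputs.  Quantitative traits
are residualized on covariates, z-scored per dataset, concatenated, and
regressed on the same dosages.

## Worked example

The analysis drivers under `analysis/` run the full study shape on
synthetic cohorts (`01` writes the cohorts, later steps read them):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_qc.py
python analysis/03_detect_blocks.py
python analysis/04_phase_and_associate.py
python analysis/05_meta_analysis.py
python analysis/06_trait_association.py
```

`04` phases the Stage-1-detected blocks in both simulated stages
(2,780/6,384 and 2,699/2,230 cases/controls) and prints, for example:

```
stage1: block omnibus p = B1 6.70e-292, B2 4.91e-06, B3 5.01e-79
  top haplotype B1e: OR 0.24 (0.20-0.28), Fisher p 7.3e-87
  top haplotype B1c: OR 2.46 (2.23-2.71), Fisher p 1.1e-74
```

i.e. every block's omnibus test is overwhelmingly significant and the
strongest per-haplotype odds ratios recover the planted protective
(OR ≈ 0.22) and risk (OR ≈ 2.51) effects.  `05` pools the two stages and
also reruns the printed-summary worked examples:

```
H1.2c: FE OR 1.23 (1.12-1.35), RE OR 1.22 (1.05-1.42), Q 2.66 (p 0.1029)
H1.2e: FE OR 1.12 (0.98-1.28), RE OR 1.12 (0.98-1.28), Q 0.61 (p 0.4353)
H1.1e: FE OR 2.38 (2.10-2.69), RE OR 1.97 (1.16-3.36), Q 6.6  (p 0.0102)
```

— pooling the two stages' published OR (95% CI) summaries reproduces the
published pooled values (FE 1.23/1.12, RE 1.22/1.97) at 2-decimal rounding.
`06` prints the expression/copy-number hits, e.g. a ~4.7-fold-elevated
haplotype detected at p ≈ 10⁻¹⁴⁴ with model R² ≈ 0.8, and the dPCR line
`lambda 1.000 vs 0.500 -> 4.00 copies per genome`.

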