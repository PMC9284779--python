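"""Synthetic case-control cohorts with known sub-haplotype structure.

The generator draws diplotypes per block under random mating (blocks are
independent by default; a clade-coupling mode links them through an H2-like
tag SNP), assigns case/control status from an additive-dosage logistic
disease model, and layers on quantitative traits (expression-like, with
covariates) and integer-ish copy-number traits.  Genotyping noise (missing
calls, single-step genotype errors) is injected separately so the QC filters
have something to find.

The disease model is prospective: P(case) = logistic(b0 + sum_h b_h * d_h)
where d_h is the individual's count (0/1/2) of haplotype h and b_h its log
odds ratio.  The default intercept corresponds to a rare-ish disease
(baseline prevalence ~2%) and cohorts are then resampled retrospectively to
fixed case/control counts; retrospective sampling leaves the odds ratios
unbiased, mirroring a case-control study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pools import HaplotypePool

DEFAULT_BASELINE_LOGIT = -4.0
MISSING = -1


@dataclass
class CohortSpec:
    """Parameters of one simulated cohort."""

    n_individuals: int
    baseline_logit: float = DEFAULT_BASELINE_LOGIT
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0
    # name -> ("normal", mean, sd) or ("bernoulli", p)
    covariate_model: dict[str, tuple] = field(
        default_factory=lambda: {
            "sex": ("bernoulli", 0.5),
            "age": ("normal", 72.0, 9.0),
            "pmi": ("normal", 12.0, 6.0),
            "rin": ("normal", 7.0, 1.0),
        }
    )

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        for r in (self.missing_rate, self.genotype_error_rate):
            if not (0 <= r < 1):
                raise ValueError("rates must lie in [0, 1)")


@dataclass
class SimulatedCohort:
    """A simulated cohort with full ground truth retained."""

    pools: list[HaplotypePool]
    # per block: (n, 2) int array of haplotype indices into pool.haplotypes
    true_diplotypes: dict[str, np.ndarray]
    genotypes: np.ndarray  # (n_samples, n_variants) int8, -1 = missing
    variants: pd.DataFrame  # chrom, pos, id, ref, alt, block
    status: np.ndarray  # 0/1
    covariates: pd.DataFrame
    traits: pd.DataFrame
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]


def sample_diplotypes(
    pool: HaplotypePool, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n unordered haplotype pairs i.i.d. from the pool (random mating).

    Returns an (n, 2) array of haplotype indices.  Deterministic for a fixed
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = np.asarray(pool.frequencies)
    return rng.choice(len(freqs), size=(n, 2), p=freqs)


def haplotype_counts(diplotypes: np.ndarray, n_haps: int) -> np.ndarray:
    """Per-individual counts (0/1/2) of each haplotype: (n, n_haps)."""
    n = diplotypes.shape[0]
    counts = np.zeros((n, n_haps), dtype=np.int8)
    rows = np.arange(n)
    np.add.at(counts, (rows, diplotypes[:, 0]), 1)
    np.add.at(counts, (rows, diplotypes[:, 1]), 1)
    return counts


def _linear_predictor(diplotypes: np.ndarray, pool: HaplotypePool) -> np.ndarray:
    betas = np.array([h.disease_log_or for h in pool.haplotypes])
    if diplotypes.max(initial=-1) >= len(betas):
        raise ValueError("diplotype refers to a haplotype not in the pool")
    return betas[diplotypes[:, 0]] + betas[diplotypes[:, 1]]


def assign_case_control(
    diplotypes: np.ndarray | dict[str, np.ndarray],
    pool: HaplotypePool | list[HaplotypePool],
    baseline_logit: float = DEFAULT_BASELINE_LOGIT,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Bernoulli case/control labels from the additive logistic model.

    Accepts a single block (array + pool) or several blocks (dict keyed by
    block_id + list of pools); effects add across blocks on the logit scale.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(diplotypes, dict):
        pools = {p.block_id: p for p in pool}
        eta = None
        for bid, dips in diplotypes.items():
            term = _linear_predictor(dips, pools[bid])
            eta = term if eta is None else eta + term
    else:
        eta = _linear_predictor(diplotypes, pool)
    p = 1.0 / (1.0 + np.exp(-(baseline_logit + eta)))
    return (rng.random(p.shape) < p).astype(np.int8)


def genotypes_from_diplotypes(
    diplotypes: np.ndarray, pool: HaplotypePool
) -> np.ndarray:
    """Unphased 0/1/2 genotypes = allele sum of the two true haplotypes.

    The alternate allele at each site is defined as the allele differing from
    the most common haplotype's allele (biallelic by pool construction).
    """
    ref = pool.reference().alleles
    alt_code = np.array(
        [[0 if a == ref[j] else 1 for j, a in enumerate(h.alleles)]
         for h in pool.haplotypes],
        dtype=np.int8,
    )
    return alt_code[diplotypes[:, 0]] + alt_code[diplotypes[:, 1]]


def pool_variant_table(pool: HaplotypePool) -> pd.DataFrame:
    """Variant table (chrom, pos, id, ref, alt) for one pool's SNPs."""
    ref_hap = pool.reference().alleles
    rows = []
    for j, pos in enumerate(pool.positions):
        alleles = {h.alleles[j] for h in pool.haplotypes}
        ref = ref_hap[j]
        alts = sorted(alleles - {ref})
        alt = alts[0] if alts else ("A" if ref != "A" else "G")
        rows.append(
            {"chrom": pool.chrom, "pos": pos,
             "id": f"{pool.block_id}_snp{j + 1}", "ref": ref, "alt": alt,
             "block": pool.block_id}
        )
    return pd.DataFrame(rows)


def add_genotyping_noise(
    genotypes: np.ndarray,
    missing_rate: float,
    error_rate: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Inject missing calls and symmetric single-step genotype errors.

    Each entry is independently set missing with ``missing_rate``; each
    remaining non-missing entry is perturbed with ``error_rate`` to an
    adjacent valid genotype (0->1, 2->1, 1->0 or 2 with equal probability).
    """
    for r in (missing_rate, error_rate):
        if not (0 <= r < 1):
            raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = genotypes.astype(np.int8, copy=True)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    if error_rate > 0:
        err = (rng.random(g.shape) < error_rate) & (g != MISSING)
        step = np.where(g == 0, 1, np.where(g == 2, -1, 0))
        coin = rng.integers(0, 2, size=g.shape) * 2 - 1  # +/-1 for hets
        step = np.where(g == 1, coin, step)
        g[err] = g[err] + step[err]
    return g


def simulate_quant_trait(
    diplotypes: np.ndarray,
    pool: HaplotypePool,
    covariate_table: pd.DataFrame | None,
    effect_scale: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    covariate_coefs: dict[str, float] | None = None,
) -> np.ndarray:
    """Expression-like trait: sum_h effect_h * dosage_h + gamma'covariates + noise.

    ``trait_effect`` in the pool is the raw-scale contribution per haplotype
    copy; with the defaults the protective haplotypes sit ~3-5 fold above the
    reference.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = haplotype_counts(diplotypes, len(pool.haplotypes))
    effects = np.array([h.trait_effect for h in pool.haplotypes]) * effect_scale
    trait = counts @ effects
    if covariate_table is not None:
        if len(covariate_table) != len(diplotypes):
            raise ValueError("covariate table not aligned with diplotypes")
        coefs = covariate_coefs or {}
        for name, gamma in coefs.items():
            trait = trait + gamma * covariate_table[name].to_numpy(float)
    if noise_sd > 0:
        trait = trait + rng.normal(0.0, noise_sd, size=trait.shape)
    return trait


def simulate_copy_number(
    diplotypes: np.ndarray,
    pool: HaplotypePool,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Copy-number traits: diploid sum of per-haplotype integer contributions.

    One column per region named in the haplotypes' ``copy_number_map``;
    Gaussian measurement noise on top when ``noise_sd > 0``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    regions = sorted({k for h in pool.haplotypes for k in h.copy_number_map})
    for h in pool.haplotypes:
        missing = [r for r in regions if r not in h.copy_number_map]
        if missing:
            raise ValueError(
                f"haplotype {h.alleles} lacks copy_number_map entries: {missing}"
            )
    out = {}
    for region in regions:
        contrib = np.array([h.copy_number_map[region] for h in pool.haplotypes],
                           dtype=float)
        vals = contrib[diplotypes[:, 0]] + contrib[diplotypes[:, 1]]
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        out[region] = vals
    return pd.DataFrame(out)


def _draw_covariates(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, model in spec.covariate_model.items():
        if model[0] == "bernoulli":
            cols[name] = rng.random(n) < model[1]
        elif model[0] == "normal":
            cols[name] = rng.normal(model[1], model[2], size=n)
        else:
            raise ValueError(f"unknown covariate model {model[0]!r}")
    return pd.DataFrame(cols).astype(float)


def simulate_cohort(
    pools: list[HaplotypePool],
    spec: CohortSpec,
    n_cases: int | None = None,
    n_controls: int | None = None,
    clade_coupling: bool = False,
    h2_frequency: float = 0.2,
    tag_position: int = 43_500_000,
    trait_noise_sd: float = 1.0,
    copy_noise_sd: float = 0.3,
) -> SimulatedCohort:
    """Simulate a full cohort across blocks, optionally at fixed case/control counts.

    With ``n_cases``/``n_controls`` given, a larger population is simulated
    prospectively and then resampled retrospectively to the requested counts
    (``spec.n_individuals`` is treated as the population size to draw from and
    grown automatically if the case quota cannot be met).

    With ``clade_coupling`` an H2-like clade of frequency ``h2_frequency`` is
    drawn per chromosome and marked by an extra biallelic tag SNP placed ahead
    of the blocks; H2 chromosomes carry, in every block, the pool's designated
    H2 haplotype if one exists (clade label "H2") and otherwise its reference
    haplotype, creating the clade/block correlation needed for H1-homozygote
    stratification.
    """
    rng = np.random.default_rng(spec.seed)
    n_pop = spec.n_individuals
    if n_cases is not None:
        n_pop = max(n_pop, 80 * (n_cases + (n_controls or 0)))

    dips = {}
    h2_carrier = None
    if clade_coupling:
        h2_carrier = rng.random((n_pop, 2)) < h2_frequency  # per chromosome
    for pool in pools:
        d = sample_diplotypes(pool, n_pop, rng)
        if clade_coupling:
            clades = [h.clade for h in pool.haplotypes]
            h2_idx = clades.index("H2") if "H2" in clades else \
                pool.haplotypes.index(pool.reference())
            d = d.copy()
            d[h2_carrier[:, 0], 0] = h2_idx
            d[h2_carrier[:, 1], 1] = h2_idx
        dips[pool.block_id] = d

    status = assign_case_control(dips, pools, spec.baseline_logit, rng)

    if n_cases is not None:
        case_idx = np.flatnonzero(status == 1)
        ctrl_idx = np.flatnonzero(status == 0)
        if len(case_idx) < n_cases or len(ctrl_idx) < (n_controls or 0):
            raise RuntimeError(
                "population too small for requested case/control counts; "
                "increase spec.n_individuals"
            )
        keep = np.concatenate([
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(ctrl_idx, size=n_controls, replace=False),
        ])
        keep.sort()
        status = status[keep]
        dips = {b: d[keep] for b, d in dips.items()}
        if h2_carrier is not None:
            h2_carrier = h2_carrier[keep]
    n = len(status)

    geno_parts, var_parts = [], []
    if clade_coupling:
        tag = (h2_carrier[:, 0].astype(np.int8) + h2_carrier[:, 1].astype(np.int8))
        geno_parts.append(tag[:, None])
        var_parts.append(pd.DataFrame([{
            "chrom": pools[0].chrom, "pos": tag_position, "id": "h2_tag",
            "ref": "A", "alt": "G", "block": "tag",
        }]))
    for pool in pools:
        geno_parts.append(genotypes_from_diplotypes(dips[pool.block_id], pool))
        var_parts.append(pool_variant_table(pool))
    genotypes = np.concatenate(geno_parts, axis=1).astype(np.int8)
    variants = pd.concat(var_parts, ignore_index=True)

    genotypes = add_genotyping_noise(
        genotypes, spec.missing_rate, spec.genotype_error_rate, rng
    )

    covariates = _draw_covariates(spec, n, rng)
    traits = {}
    for pool in pools:
        traits[f"expr_{pool.block_id}"] = simulate_quant_trait(
            dips[pool.block_id], pool, covariates,
            noise_sd=trait_noise_sd, seed=rng,
            covariate_coefs={"age": 0.01, "rin": 0.05},
        )
    cn = simulate_copy_number(dips[pools[0].block_id], pools[0],
                              noise_sd=copy_noise_sd, seed=rng)
    for col in cn.columns:
        traits[f"cn_{col}"] = cn[col].to_numpy()

    return SimulatedCohort(
        pools=list(pools),
        true_diplotypes=dips,
        genotypes=genotypes,
        variants=variants,
        status=np.asarray(status, dtype=np.int8),
        covariates=covariates,
        traits=pd.DataFrame(traits),
        sample_ids=[f"S{i:06d}" for i in range(n)],
    )
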