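"""EM haplotype frequency estimation within blocks.

Haplotypes over a block of m <= 15 biallelic SNPs are coded as m-bit integers
(bit j set = alternate allele at SNP j).  The haplotype universe is the union
over individuals of the haplotypes compatible with their observed genotypes
(heterozygous sites take either allele on either chromosome; missing sites
are summed over).  The EM runs on unique genotype patterns weighted by their
multiplicities, which makes cohort-scale estimation cheap, and exposes the
standard E-step by-products: per-individual diplotype posteriors and
expected haplotype dosages, the additive regressors used downstream.

Defaults follow common practice for this analysis: at most 50 iterations
with a convergence tolerance of 1e-4 on the largest frequency change;
haplotypes rarer than 0.01 are pruned from reporting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
MAX_CANDIDATE_HAPLOTYPES = 100_000


@dataclass
class HaplotypeSet:
    """Estimated haplotype frequencies and phasing by-products for one block."""

    block_id: str
    n_snps: int
    haplotype_codes: np.ndarray  # int codes, aligned with frequencies
    frequencies: np.ndarray
    loglik_trace: list[float]
    converged: bool
    # per retained individual: index into sample axis, pattern id
    sample_index: np.ndarray  # indices of individuals that were phased
    pattern_of_sample: np.ndarray  # pattern id per retained individual
    # pattern-level pair structure (shared by all individuals with a pattern)
    pair_pattern: np.ndarray  # pattern id per pair
    pair_h1: np.ndarray  # haplotype index per pair
    pair_h2: np.ndarray
    excluded_samples: list[int] = field(default_factory=list)
    pruned_mask: np.ndarray | None = None  # True where haplotype pruned

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_codes)

    def allele_strings(self, ref_alleles: str | None = None,
                       alt_alleles: str | None = None) -> list[str]:
        """Haplotype codes rendered as allele strings (default: 0/1 digits)."""
        out = []
        for code in self.haplotype_codes:
            bits = [(int(code) >> j) & 1 for j in range(self.n_snps)]
            if ref_alleles is None:
                out.append("".join(str(b) for b in bits))
            else:
                out.append("".join(
                    alt_alleles[j] if b else ref_alleles[j]
                    for j, b in enumerate(bits)
                ))
        return out

    def labels(self, ref_alleles: str | None = None,
               alt_alleles: str | None = None) -> list[str]:
        """Frequency-ranked labels: block_id + a, b, c ... by descending
        frequency, ties broken lexicographically by allele string."""
        strings = self.allele_strings(ref_alleles, alt_alleles)
        order = sorted(range(self.n_haplotypes),
                       key=lambda k: (-self.frequencies[k], strings[k]))
        labels = [""] * self.n_haplotypes
        for rank, k in enumerate(order):
            labels[k] = f"{self.block_id}{chr(ord('a') + rank)}"
        return labels

    def reference_index(self) -> int:
        """Index of the most common haplotype (the association reference)."""
        strings = self.allele_strings()
        return min(range(self.n_haplotypes),
                   key=lambda k: (-self.frequencies[k], strings[k]))


def _compatible_pairs(pattern: np.ndarray) -> list[tuple[int, int]]:
    """All unordered haplotype-code pairs compatible with one genotype pattern."""
    options = []
    for g in pattern:
        if g == 0:
            options.append(((0, 0),))
        elif g == 2:
            options.append(((1, 1),))
        elif g == 1:
            options.append(((0, 1), (1, 0)))
        elif g == MISSING:
            options.append(((0, 0), (0, 1), (1, 0), (1, 1)))
        else:
            raise ValueError(f"invalid genotype {g}")
    pairs = set()
    for combo in itertools.product(*options):
        h1 = h2 = 0
        for j, (a, b) in enumerate(combo):
            h1 |= a << j
            h2 |= b << j
        pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(pairs)


def _initial_frequencies(genotypes: np.ndarray, codes: np.ndarray,
                         n_snps: int) -> np.ndarray:
    """Allele-frequency product start, blended with uniform for stability."""
    with np.errstate(invalid="ignore"):
        p_alt = np.array([
            genotypes[genotypes[:, j] >= 0, j].mean() / 2.0
            if (genotypes[:, j] >= 0).any() else 0.5
            for j in range(n_snps)
        ])
    p_alt = np.clip(p_alt, 1e-6, 1 - 1e-6)
    f = np.ones(len(codes))
    for j in range(n_snps):
        bit = (codes >> j) & 1
        f *= np.where(bit == 1, p_alt[j], 1 - p_alt[j])
    f = 0.9 * f / f.sum() + 0.1 / len(codes)
    return f


def em_haplotype_freqs(
    genotypes: np.ndarray,
    block_id: str = "block",
    max_iter: int = 50,
    tol: float = 1e-4,
) -> HaplotypeSet:
    """EM haplotype frequency estimation for one block of unphased genotypes.

    Parameters
    ----------
    genotypes:
        (n_samples, n_snps) array of 0/1/2 alternate-allele counts, -1 for a
        missing call.  n_snps must be <= 15 (the block contract).
    max_iter, tol:
        Iteration cap and convergence tolerance on the maximum absolute
        frequency change.  A warning is logged if the cap is hit first.

    Individuals with every genotype missing are excluded (logged).  The EM
    log-likelihood is non-decreasing by construction; the trace is kept on
    the result for verification.
    """
    genotypes = np.asarray(genotypes)
    n, m = genotypes.shape
    if m > 15:
        raise ValueError("block contract: at most 15 markers")
    all_missing = (genotypes == MISSING).all(axis=1)
    excluded = np.flatnonzero(all_missing).tolist()
    if excluded:
        logger.info("excluding %d individuals with no genotypes", len(excluded))
    keep = np.flatnonzero(~all_missing)
    g = genotypes[keep]
    if len(g) == 0:
        raise ValueError("no individuals with any genotype calls")

    patterns, pattern_of_sample = np.unique(g, axis=0, return_inverse=True)
    pattern_weight = np.bincount(pattern_of_sample).astype(float)

    pair_lists = [_compatible_pairs(p) for p in patterns]
    universe = sorted({h for pl in pair_lists for pr in pl for h in pr})
    if len(universe) > MAX_CANDIDATE_HAPLOTYPES:
        raise RuntimeError(
            f"candidate haplotype universe too large ({len(universe)}); "
            "genotype missingness is pathological for exact EM"
        )
    codes = np.array(universe, dtype=np.int64)
    code_index = {h: k for k, h in enumerate(universe)}

    pair_pattern = np.concatenate([
        np.full(len(pl), pi, dtype=np.int64)
        for pi, pl in enumerate(pair_lists)
    ])
    pair_h1 = np.array([code_index[a] for pl in pair_lists for a, _ in pl])
    pair_h2 = np.array([code_index[b] for pl in pair_lists for _, b in pl])
    het_mult = np.where(pair_h1 != pair_h2, 2.0, 1.0)

    f = _initial_frequencies(g, codes, m)
    two_n = 2.0 * pattern_weight.sum()
    n_patterns = len(patterns)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        pair_lik = het_mult * f[pair_h1] * f[pair_h2]
        pattern_lik = np.bincount(pair_pattern, weights=pair_lik,
                                  minlength=n_patterns)
        trace.append(float(np.dot(pattern_weight,
                                  np.log(np.clip(pattern_lik, 1e-300, None)))))
        resp = pair_lik / np.clip(pattern_lik[pair_pattern], 1e-300, None)
        w = resp * pattern_weight[pair_pattern]
        counts = (np.bincount(pair_h1, weights=w, minlength=len(codes))
                  + np.bincount(pair_h2, weights=w, minlength=len(codes)))
        new = counts / two_n
        if np.max(np.abs(new - f)) < tol:
            f = new
            converged = True
            break
        f = new
    if not converged:
        logger.warning("EM hit the %d-iteration cap before tol=%g (block %s)",
                       max_iter, tol, block_id)
    # final log-likelihood at the returned frequencies
    pair_lik = het_mult * f[pair_h1] * f[pair_h2]
    pattern_lik = np.bincount(pair_pattern, weights=pair_lik,
                              minlength=n_patterns)
    trace.append(float(np.dot(pattern_weight,
                              np.log(np.clip(pattern_lik, 1e-300, None)))))

    return HaplotypeSet(
        block_id=block_id,
        n_snps=m,
        haplotype_codes=codes,
        frequencies=f,
        loglik_trace=trace,
        converged=converged,
        sample_index=keep,
        pattern_of_sample=pattern_of_sample,
        pair_pattern=pair_pattern,
        pair_h1=pair_h1,
        pair_h2=pair_h2,
        excluded_samples=excluded,
    )


def diplotype_posteriors(hapset: HaplotypeSet, individual: int) -> pd.DataFrame:
    """Posterior over compatible haplotype pairs for one retained individual.

    P(pair) is proportional to f_h1 * f_h2, doubled for heterozygous pairs,
    normalized over the individual's compatible pairs.
    """
    pos = np.flatnonzero(hapset.sample_index == individual)
    if len(pos) == 0:
        raise ValueError(f"individual {individual} was not phased")
    pat = hapset.pattern_of_sample[pos[0]]
    sel = hapset.pair_pattern == pat
    h1 = hapset.pair_h1[sel]
    h2 = hapset.pair_h2[sel]
    f = hapset.frequencies
    w = f[h1] * f[h2] * np.where(h1 != h2, 2.0, 1.0)
    total = w.sum()
    if total <= 0:
        w = np.ones_like(w)
        total = w.sum()
    return pd.DataFrame({"h1": h1, "h2": h2, "posterior": w / total})


def haplotype_dosages(hapset: HaplotypeSet, n_samples: int | None = None
                      ) -> np.ndarray:
    """Expected haplotype counts per individual: (n_samples, n_haplotypes).

    Rows of excluded (all-missing) individuals are NaN; retained rows sum
    to 2.
    """
    f = hapset.frequencies
    h1, h2 = hapset.pair_h1, hapset.pair_h2
    w = f[h1] * f[h2] * np.where(h1 != h2, 2.0, 1.0)
    n_pat = hapset.pattern_of_sample.max() + 1 if len(hapset.pattern_of_sample) else 0
    pattern_tot = np.bincount(hapset.pair_pattern, weights=w, minlength=n_pat)
    resp = w / np.clip(pattern_tot[hapset.pair_pattern], 1e-300, None)
    H = hapset.n_haplotypes
    pat_dosage = np.zeros((n_pat, H))
    np.add.at(pat_dosage, (hapset.pair_pattern, h1), resp)
    np.add.at(pat_dosage, (hapset.pair_pattern, h2), resp)
    if n_samples is None:
        n_samples = (int(hapset.sample_index.max()) + 1
                     if len(hapset.sample_index) else 0)
        n_samples = max(n_samples, len(hapset.sample_index)
                        + len(hapset.excluded_samples))
    out = np.full((n_samples, H), np.nan)
    out[hapset.sample_index] = pat_dosage[hapset.pattern_of_sample]
    return out


def prune_rare(hapset: HaplotypeSet, min_freq: float = 0.01) -> HaplotypeSet:
    """Mark haplotypes with frequency below ``min_freq`` as pruned.

    Pruned haplotypes are dropped from reporting and association; the
    remaining frequencies are deliberately NOT renormalized (raw scale
    retained).  Individuals whose posterior mass falls mostly (> 0.5) on
    pruned haplotypes are logged as flagged.
    """
    mask = hapset.frequencies < min_freq
    if mask.all():
        raise ValueError("all haplotypes fall below the frequency threshold")
    if mask.any():
        dosages = haplotype_dosages(hapset)
        pruned_mass = np.nansum(dosages[:, mask], axis=1) / 2.0
        flagged = np.flatnonzero(pruned_mass > 0.5)
        if len(flagged):
            logger.info("prune_rare: %d individuals carry mostly-pruned "
                        "haplotypes", len(flagged))
    out = HaplotypeSet(**{**hapset.__dict__})
    out.pruned_mask = mask
    return out


def retained_indices(hapset: HaplotypeSet) -> np.ndarray:
    """Indices of non-pruned haplotypes (all, if prune_rare was not run)."""
    if hapset.pruned_mask is None:
        return np.arange(hapset.n_haplotypes)
    return np.flatnonzero(~hapset.pruned_mask)


def call_tag_snp_clades(
    genotypes: np.ndarray,
    tag_variant: int,
    clade_names: tuple[str, str] = ("H1", "H2"),
) -> pd.Series:
    """Label samples by tag-SNP genotype: ref-clade/alt-clade diplotypes.

    Genotype 0 -> "H1/H1", 1 -> "H1/H2", 2 -> "H2/H2" (with the default
    names); missing tag genotypes yield NA and are excluded from stratified
    analyses.
    """
    g = np.asarray(genotypes)[:, tag_variant]
    a, b = clade_names
    labels = {0: f"{a}/{a}", 1: f"{a}/{b}", 2: f"{b}/{b}"}
    out = pd.Series([labels.get(int(x)) if x >= 0 else None for x in g],
                    dtype="object")
    n_missing = int((g < 0).sum())
    if n_missing:
        logger.info("tag SNP missing in %d samples; excluded from "
                    "stratification", n_missing)
    return out


def homozygote_subset(clades: pd.Series, clade: str = "H1") -> np.ndarray:
    """Indices of samples homozygous for the given clade."""
    return np.flatnonzero(clades == f"{clade}/{clade}")


def write_haplotype_tsv(hapset: HaplotypeSet, path,
                        ref_alleles: str | None = None,
                        alt_alleles: str | None = None) -> None:
    """Serialize retained haplotypes as TSV (haplotype, label, frequency)."""
    idx = retained_indices(hapset)
    strings = hapset.allele_strings(ref_alleles, alt_alleles)
    labels = hapset.labels(ref_alleles, alt_alleles)
    pd.DataFrame({
        "haplotype": [strings[k] for k in idx],
        "label": [labels[k] for k in idx],
        "frequency": hapset.frequencies[idx],
    }).to_csv(path, sep="\t", index=False)
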