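"""Genotype quality control: call-rate, MAF, HWE-exact, IBD, PCA, INFO filters.

The filter chain mirrors a standard pre-imputation pipeline and is applied
in a fixed order: variant call rate (>= 98%), minor allele frequency
(>= 1%), sample call rate (>= 98%), relatedness (method-of-moments IBD;
pairs with Z0 <= 0.8 flagged), Hardy-Weinberg exact test (p < 1e-4 removed),
then an optional per-variant imputation-quality (INFO/r2) filter.  Every
step logs counts in/out into a :class:`QCReport` so the narrative of the
filtering can be reconstructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class FilterStep:
    name: str
    axis: str  # "variant" | "sample" | "pair"
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class QCReport:
    steps: list[FilterStep] = field(default_factory=list)

    def log(self, name: str, axis: str, n_in: int, n_removed: int) -> None:
        self.steps.append(FilterStep(name, axis, n_in, n_removed))
        logger.info("QC %s (%s): %d in, %d removed, %d out",
                    name, axis, n_in, n_removed, n_in - n_removed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ | {"n_out": s.n_out}
                             for s in self.steps])


@dataclass
class IBDResult:
    pair: tuple[int, int]
    Z0: float
    Z1: float
    Z2: float

    @property
    def pi_hat(self) -> float:
        return self.Z1 / 2.0 + self.Z2


def _call_rates(genotypes: np.ndarray, axis: int) -> np.ndarray:
    return (genotypes != MISSING).mean(axis=axis)


def filter_variant_call_rate(
    genotypes: np.ndarray, threshold: float = 0.98,
    report: QCReport | None = None,
) -> np.ndarray:
    """Boolean mask of variants whose non-missing fraction is >= threshold."""
    if genotypes.size == 0:
        raise ValueError("empty genotype matrix")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    keep = _call_rates(genotypes, axis=0) >= threshold
    if report is not None:
        report.log("variant_call_rate", "variant", len(keep),
                   int((~keep).sum()))
    return keep


def filter_sample_call_rate(
    genotypes: np.ndarray, threshold: float = 0.98,
    report: QCReport | None = None,
) -> np.ndarray:
    """Boolean mask of samples (rows) with call rate >= threshold."""
    if genotypes.size == 0:
        raise ValueError("empty genotype matrix")
    keep = _call_rates(genotypes, axis=1) >= threshold
    if report is not None:
        report.log("sample_call_rate", "sample", len(keep), int((~keep).sum()))
    return keep


def minor_allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Per-variant MAF on non-missing chromosomes (0 where all missing)."""
    g = np.ma.masked_equal(genotypes, MISSING)
    p_alt = g.mean(axis=0).filled(0.0) / 2.0
    return np.minimum(p_alt, 1.0 - p_alt)


def filter_maf(
    genotypes: np.ndarray, threshold: float = 0.01,
    report: QCReport | None = None,
) -> np.ndarray:
    """Boolean mask of variants with MAF >= threshold (boundary kept)."""
    maf = minor_allele_frequencies(genotypes)
    keep = maf >= threshold
    if report is not None:
        report.log("maf", "variant", len(keep), int((~keep).sum()))
    return keep


def _hwe_log_prob(n_het: np.ndarray, n: int, n_a: int) -> np.ndarray:
    """log P(n_het heterozygotes | n genotypes, n_a minor alleles) under HWE."""
    n_hom_a = (n_a - n_het) // 2
    n_hom_b = n - n_het - n_hom_a
    return (gammaln(n + 1) - gammaln(n_hom_a + 1) - gammaln(n_het + 1)
            - gammaln(n_hom_b + 1) + n_het * np.log(2.0)
            + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1) - gammaln(2 * n + 1))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided by heterozygote probability).

    Conditional on the allele counts, the p-value is the total probability of
    heterozygote counts no more probable than the observed one.  Monomorphic
    variants return 1.0.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele count
    if n_a == 0:
        return 1.0
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = _hwe_log_prob(hets, n, n_a)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def filter_hwe(
    genotypes: np.ndarray, threshold: float = 1e-4,
    report: QCReport | None = None,
) -> np.ndarray:
    """Boolean mask of variants NOT deviating from HWE at p < threshold."""
    m = genotypes.shape[1]
    keep = np.ones(m, dtype=bool)
    for j in range(m):
        g = genotypes[:, j]
        g = g[g != MISSING]
        n_aa = int((g == 2).sum())
        n_het = int((g == 1).sum())
        n_AA = int((g == 0).sum())
        if n_AA + n_het + n_aa == 0:
            keep[j] = False
            continue
        keep[j] = hwe_exact_test(n_AA, n_het, n_aa) >= threshold
    if report is not None:
        report.log("hwe", "variant", m, int((~keep).sum()))
    return keep


def _allele_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant (alt allele count, total allele count) over called genotypes."""
    called = genotypes != MISSING
    alt = np.where(called, genotypes, 0).sum(axis=0).astype(float)
    tot = 2.0 * called.sum(axis=0)
    return alt, tot


def estimate_ibd(genotypes: np.ndarray, pair: tuple[int, int],
                 allele_counts: tuple[np.ndarray, np.ndarray] | None = None,
                 ) -> IBDResult:
    """Method-of-moments IBD estimate (Z0, Z1, Z2) for one sample pair.

    IBS counts across variants called in both samples are compared with
    their expectations under IBD states 0/1/2.  The expectations use
    unbiased estimators of the allele-probability monomials (p^2*q^2 etc.)
    from the sample allele counts, which removes the finite-sample bias of
    plugging in estimated frequencies.  The Z estimates are truncated to
    [0, 1] and renormalized.  Duplicates give PI_HAT near 1, unrelated
    pairs Z0 near 1.
    """
    i, j = pair
    gi, gj = genotypes[i], genotypes[j]
    ok = (gi != MISSING) & (gj != MISSING)
    if allele_counts is None:
        X, a = _allele_counts(genotypes)
    else:
        X, a = allele_counts
    # restrict to informative variants: polymorphic, both called
    ok &= (X > 0) & (X < a) & (a >= 4)
    if ok.sum() < 20:
        raise ValueError("insufficient overlapping informative variants")
    gi, gj = gi[ok], gj[ok]
    X, a = X[ok], a[ok]
    Y = a - X

    def falling(v, k):
        out = np.ones_like(v)
        for t in range(k):
            out = out * (v - t)
        return out

    # unbiased estimators of p^r q^s from X alt alleles out of a
    def mono(r, s):
        return falling(X, r) * falling(Y, s) / falling(a, r + s)

    ibs0 = ((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))
    ibs2 = gi == gj
    N0 = float(ibs0.sum())
    N2 = float(ibs2.sum())
    N1 = float(len(gi) - N0 - N2)
    e0_z0 = float(np.sum(2 * mono(2, 2)))
    e1_z0 = float(np.sum(4 * mono(3, 1) + 4 * mono(1, 3)))
    e2_z0 = float(np.sum(mono(4, 0) + mono(0, 4) + 4 * mono(2, 2)))
    e1_z1 = float(np.sum(2 * mono(1, 1)))
    e2_z1 = float(np.sum(mono(2, 0) + mono(0, 2)))
    n_var = float(len(gi))
    Z0 = N0 / e0_z0 if e0_z0 > 0 else 0.0
    Z1 = (N1 - Z0 * e1_z0) / e1_z1 if e1_z1 > 0 else 0.0
    Z2 = (N2 - Z0 * e2_z0 - Z1 * e2_z1) / n_var
    z = np.array([Z0, Z1, Z2])
    # bound to the simplex: negatives to 0 (others rescaled), overshoots to
    # the corresponding corner
    for k in range(3):
        if z[k] > 1:
            z = np.zeros(3)
            z[k] = 1.0
            break
    if (z < 0).any():
        z = np.clip(z, 0.0, None)
        s = z.sum()
        z = z / s if s > 0 else np.array([1.0, 0.0, 0.0])
    return IBDResult(pair=(i, j), Z0=float(z[0]), Z1=float(z[1]), Z2=float(z[2]))


def flag_related_pairs(
    genotypes: np.ndarray, z0_threshold: float = 0.8,
    report: QCReport | None = None,
) -> list[IBDResult]:
    """All sample pairs with Z0 <= threshold (duplicates/relatives)."""
    n = genotypes.shape[0]
    counts = _allele_counts(genotypes)
    flagged = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            try:
                r = estimate_ibd(genotypes, (i, j), allele_counts=counts)
            except ValueError:
                continue
            if r.Z0 <= z0_threshold:
                flagged.append(r)
    if report is not None:
        report.log("ibd_z0", "pair", n * (n - 1) // 2, len(flagged))
    return flagged


def pca_covariates(genotypes: np.ndarray, k: int = 10) -> np.ndarray:
    """Top-k principal component scores for use as regression covariates.

    Variants are standardized by mean 2p and sd sqrt(2p(1-p)); missing
    entries are mean-imputed (zero after centering).  Columns are orthogonal;
    the sign convention makes each component's largest-magnitude variant
    loading positive.
    """
    g = np.asarray(genotypes, dtype=float)
    miss = g == MISSING
    g = np.where(miss, np.nan, g)
    p = np.nanmean(g, axis=0) / 2.0
    sd = np.sqrt(2 * p * (1 - p))
    poly = sd > 0
    x = (g[:, poly] - 2 * p[poly]) / sd[poly]
    x = np.nan_to_num(x, nan=0.0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    if k > rank:
        logger.warning("requested %d PCs but rank is %d; returning %d",
                       k, rank, rank)
        k = rank
    scores = u[:, :k] * s[:k]
    for c in range(k):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            scores[:, c] *= -1
    return scores


def filter_info_score(
    variant_table: pd.DataFrame, threshold: float = 0.3,
    column: str = "info", report: QCReport | None = None,
) -> np.ndarray:
    """Boolean mask keeping variants with imputation quality >= threshold.

    Pass-through (all kept, warning logged) when the column is absent.
    """
    m = len(variant_table)
    if column not in variant_table.columns:
        logger.warning("no %r column: INFO filter skipped", column)
        keep = np.ones(m, dtype=bool)
    else:
        keep = (variant_table[column].to_numpy(float) >= threshold)
    if report is not None:
        report.log("info_score", "variant", m, int((~keep).sum()))
    return keep


def run_qc_chain(
    genotypes: np.ndarray,
    variant_table: pd.DataFrame | None = None,
    call_rate_variant: float = 0.98,
    maf: float = 0.01,
    call_rate_sample: float = 0.98,
    hwe_p: float = 1e-4,
    ibd_z0: float = 0.8,
    info_threshold: float = 0.3,
    check_ibd: bool = True,
) -> tuple[np.ndarray, np.ndarray, QCReport]:
    """The full filter chain in its canonical order.

    Returns (variant_keep_mask, sample_keep_mask, report), with masks indexed
    on the ORIGINAL axes.  Order: variant call rate -> MAF -> sample call
    rate -> IBD -> HWE -> INFO.
    """
    report = QCReport()
    n, m = genotypes.shape
    vkeep = np.ones(m, dtype=bool)
    skeep = np.ones(n, dtype=bool)

    step = filter_variant_call_rate(genotypes, call_rate_variant, report)
    vkeep &= step
    g = genotypes[:, vkeep]

    step = filter_maf(g, maf, report)
    vkeep[vkeep] &= step
    g = genotypes[:, vkeep]

    step = filter_sample_call_rate(g, call_rate_sample, report)
    skeep &= step
    g = genotypes[np.ix_(skeep, vkeep)]

    if check_ibd and g.shape[0] <= 2000:
        flagged = flag_related_pairs(g, ibd_z0, report)
        drop_local = sorted({r.pair[1] for r in flagged})
        if drop_local:
            idx = np.flatnonzero(skeep)
            skeep[idx[drop_local]] = False
            g = genotypes[np.ix_(skeep, vkeep)]

    step = filter_hwe(g, hwe_p, report)
    vkeep[vkeep] &= step

    if variant_table is not None:
        step = filter_info_score(variant_table.loc[vkeep], info_threshold,
                                 report=report)
        vkeep[vkeep] &= step

    return vkeep, skeep, report
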