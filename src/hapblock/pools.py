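"""Ancestral haplotype pools: the ground truth behind the synthetic cohorts.

A :class:`HaplotypePool` describes one sub-haplotype block at the 17q21.31
locus as a small set of ancestral allele strings with population frequencies,
per-haplotype disease effects (log odds ratios relative to the most common
haplotype), raw-scale expression effects and integer copy-number
contributions for the structurally variable regions at the distal end of the
locus.  The defaults encode the three blocks spanning *MAPT* and *KANSL1*
(H1.1, H1.2, H1.3) with their published Stage 1 frequencies and odds ratios,
so that the downstream pipeline can be exercised end to end on data whose
truth is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Haplotype:
    """One ancestral haplotype within a block."""

    alleles: str
    frequency: float
    clade: str = "H1"
    disease_log_or: float = 0.0
    trait_effect: float = 1.0
    copy_number_map: dict[str, int] = field(default_factory=dict)


@dataclass
class HaplotypePool:
    """A block of tightly linked SNPs and its ancestral haplotypes.

    Parameters
    ----------
    block_id:
        Label for the block, e.g. ``"H1.1"``.
    positions:
        1-based genomic coordinates (bp) of the member SNPs, sorted.
    haplotypes:
        Ancestral haplotypes.  Frequencies must be positive and sum to one;
        every allele string must have one character per position.
    """

    block_id: str
    positions: list[int]
    haplotypes: list[Haplotype]
    chrom: str = "17"

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError(f"pool {self.block_id}: no haplotypes")
        total = sum(h.frequency for h in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"pool {self.block_id}: frequencies sum to {total!r}, not 1"
            )
        m = len(self.positions)
        for h in self.haplotypes:
            if len(h.alleles) != m:
                raise ValueError(
                    f"pool {self.block_id}: haplotype {h.alleles} has "
                    f"{len(h.alleles)} alleles for {m} positions"
                )
            if h.frequency <= 0:
                raise ValueError(f"pool {self.block_id}: non-positive frequency")
        if sorted(self.positions) != list(self.positions):
            raise ValueError(f"pool {self.block_id}: positions not sorted")

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    @property
    def frequencies(self) -> list[float]:
        return [h.frequency for h in self.haplotypes]

    @property
    def allele_strings(self) -> list[str]:
        return [h.alleles for h in self.haplotypes]

    def reference(self) -> Haplotype:
        """The designated reference haplotype (disease log-OR 0).

        The first listed haplotype carrying log-OR 0 — the published "a"
        haplotype of each block, against which odds ratios are expressed.
        Falls back to the most common haplotype if none carries log-OR 0.
        """
        for h in self.haplotypes:
            if h.disease_log_or == 0.0:
                return h
        return max(self.haplotypes, key=lambda h: (h.frequency, h.alleles))


def _hap(alleles, freq, or_, trait=1.0, gamma=1, lrr=3):
    return Haplotype(
        alleles=alleles,
        frequency=freq,
        disease_log_or=math.log(or_),
        trait_effect=trait,
        copy_number_map={"gamma": gamma, "lrrc37a": lrr},
    )


def _spread(start: int, stop: int, k: int) -> list[int]:
    """k distinct integer positions evenly placed across [start, stop]."""
    if k == 1:
        return [start]
    step = (stop - start) / (k - 1)
    return [int(round(start + i * step)) for i in range(k)]


def build_default_pools() -> list[HaplotypePool]:
    """The three default sub-haplotype blocks with published effect sizes.

    Returns pools H1.1 (5 SNPs), H1.2 (8 SNPs) and H1.3 (9 SNPs) with Stage 1
    frequencies, disease odds ratios relative to the most common haplotype
    (which carries log-OR 0), raw-scale expression effects (protective
    haplotypes ~3-5 fold elevated) and gamma / LRRC37A-region copy-number
    contributions per haplotype copy.

    H1.3's printed frequencies sum to 0.99; they are renormalized so the pool
    is a proper distribution while preserving the relative frequencies.
    """
    h11 = HaplotypePool(
        block_id="H1.1",
        positions=_spread(44_040_184, 44_041_992, 5),
        haplotypes=[
            _hap("ACTCT", 0.25, 1.00),
            _hap("ACTTG", 0.27, 1.60, gamma=2, lrr=4),
            _hap("GCCTG", 0.18, 0.37, trait=4.7, gamma=2, lrr=5),
            _hap("ATCTG", 0.18, 0.22),
            _hap("ACCTG", 0.12, 2.51),
        ],
    )
    h12 = HaplotypePool(
        block_id="H1.2",
        positions=_spread(44_090_196, 44_097_249, 8),
        haplotypes=[
            _hap("TTTCGATG", 0.48, 1.00),
            _hap("TCTCGATG", 0.17, 1.27, trait=5.0, gamma=2, lrr=5),
            _hap("TTAAAATA", 0.15, 1.31),
            _hap("TTAAGATG", 0.07, 1.36),
            _hap("CTTCGATG", 0.06, 1.17),
            _hap("TTTCGGTG", 0.05, 1.16),
            _hap("TTAAAATG", 0.01, 1.10),
            _hap("TTTCGACG", 0.01, 1.28),
        ],
    )
    f13 = [0.28, 0.18, 0.17, 0.15, 0.09, 0.08, 0.04]
    tot = sum(f13)
    f13 = [f / tot for f in f13]
    h13 = HaplotypePool(
        block_id="H1.3",
        positions=_spread(44_119_987, 44_131_305, 9),
        haplotypes=[
            _hap("GACTGAGAT", f13[0], 1.00),
            _hap("CATTAGGGC", f13[1], 0.43, trait=5.0, gamma=2, lrr=5),
            _hap("GATTGAGAT", f13[2], 1.11),
            _hap("CTTTGGTGC", f13[3], 0.61),
            _hap("CATTGGGGC", f13[4], 1.67, trait=2.9, gamma=2, lrr=4),
            _hap("CATTGGGGT", f13[5], 0.60),
            _hap("GATCGAGAT", f13[6], 0.83),
        ],
    )
    return [h11, h12, h13]
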