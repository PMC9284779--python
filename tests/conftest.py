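import numpy as np
import pytest

from hapblock import pools as pools_mod
from hapblock import simulate
from hapblock.pools import Haplotype, HaplotypePool


@pytest.fixture(scope="session")
def default_pools():
    return pools_mod.build_default_pools()


@pytest.fixture(scope="session")
def pool_h11(default_pools):
    return default_pools[0]


@pytest.fixture(scope="session")
def pool_h12(default_pools):
    return default_pools[1]


def make_null_pool(pool: HaplotypePool) -> HaplotypePool:
    """Same haplotype structure, all disease effects zeroed."""
    return HaplotypePool(
        block_id=pool.block_id,
        positions=list(pool.positions),
        haplotypes=[
            Haplotype(h.alleles, h.frequency, h.clade, 0.0, h.trait_effect,
                      dict(h.copy_number_map))
            for h in pool.haplotypes
        ],
    )


def ladder_pool(block_id: str, freqs, positions) -> HaplotypePool:
    """Perfect-phylogeny ('ladder') pool: haplotype k has 1s at the first k
    sites, so every pair of sites shows at most three gametes (D' = 1)."""
    m = len(freqs) - 1
    haps = []
    for k, f in enumerate(freqs):
        alleles = "".join("G" if j < k else "A" for j in range(m))
        haps.append(Haplotype(alleles, f))
    return HaplotypePool(block_id=block_id, positions=list(positions),
                         haplotypes=haps)


def truth_codes(pool: HaplotypePool) -> dict[str, int]:
    """Map each pool haplotype's allele string to its 0/1 alt coding."""
    ref = pool.reference().alleles
    out = {}
    for h in pool.haplotypes:
        code = "".join("0" if a == ref[j] else "1"
                       for j, a in enumerate(h.alleles))
        out[h.alleles] = code
    return out


def phased_chromosomes(diplotypes: np.ndarray, pool: HaplotypePool
                       ) -> np.ndarray:
    """True phased chromosomes as a (2n, m) 0/1 alt-allele matrix."""
    ref = pool.reference().alleles
    alt = np.array([[0 if a == ref[j] else 1
                     for j, a in enumerate(h.alleles)]
                    for h in pool.haplotypes], dtype=np.int8)
    return alt[diplotypes.reshape(-1)]


@pytest.fixture
def small_cohort(pool_h11):
    d = simulate.sample_diplotypes(pool_h11, 300, seed=5)
    g = simulate.genotypes_from_diplotypes(d, pool_h11)
    return d, g
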