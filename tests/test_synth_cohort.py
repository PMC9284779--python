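"""Generator contracts: pool invariants, sampling, disease model, noise,
traits, copy number, and file round-trips."""

import math

import numpy as np
import pandas as pd
import pytest

from hapblock import io, simulate
from hapblock.pools import Haplotype, HaplotypePool, build_default_pools

from conftest import phased_chromosomes


class TestDefaultPools:
    def test_three_blocks_with_published_structure(self, default_pools):
        ids = [p.block_id for p in default_pools]
        assert ids == ["H1.1", "H1.2", "H1.3"]
        assert [p.n_snps for p in default_pools] == [5, 8, 9]
        for p in default_pools:
            assert abs(sum(p.frequencies) - 1.0) < 1e-9

    def test_h11_frequencies(self, pool_h11):
        freqs = {h.alleles: h.frequency for h in pool_h11.haplotypes}
        assert freqs == {"ACTCT": 0.25, "ACTTG": 0.27, "GCCTG": 0.18,
                         "ATCTG": 0.18, "ACCTG": 0.12}

    def test_h11e_odds_ratio(self, pool_h11):
        h11e = next(h for h in pool_h11.haplotypes if h.alleles == "ACCTG")
        assert math.exp(h11e.disease_log_or) == pytest.approx(2.51)

    def test_reference_haplotypes_carry_zero_log_or(self, default_pools):
        for p in default_pools:
            assert p.reference().disease_log_or == 0.0

    def test_positions_lie_within_block_spans(self, default_pools):
        spans = [(44_040_184, 44_041_992), (44_090_196, 44_097_249),
                 (44_119_987, 44_131_305)]
        for p, (lo, hi) in zip(default_pools, spans):
            assert min(p.positions) >= lo and max(p.positions) <= hi

    def test_invalid_pools_rejected(self):
        with pytest.raises(ValueError):
            HaplotypePool("x", [1, 2], [Haplotype("AA", 0.5)])
        with pytest.raises(ValueError):
            HaplotypePool("x", [1, 2],
                          [Haplotype("AAA", 0.5), Haplotype("CCC", 0.5)])


class TestSampleDiplotypes:
    def test_degenerate_pool_gives_identical_pairs(self):
        pool = HaplotypePool("solo", [1, 2], [Haplotype("AC", 1.0)])
        d = simulate.sample_diplotypes(pool, 10, seed=0)
        assert (d == 0).all()

    def test_same_seed_reproduces(self, pool_h11):
        a = simulate.sample_diplotypes(pool_h11, 50, seed=42)
        b = simulate.sample_diplotypes(pool_h11, 50, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_empirical_frequencies_converge(self, pool_h11):
        d = simulate.sample_diplotypes(pool_h11, 5000, seed=1)
        emp = np.bincount(d.reshape(-1), minlength=5) / 10_000
        np.testing.assert_allclose(emp, pool_h11.frequencies, atol=0.02)


class TestDiseaseModel:
    def test_null_effects_give_half_cases(self, pool_h11):
        from conftest import make_null_pool

        null = make_null_pool(pool_h11)
        d = simulate.sample_diplotypes(null, 5000, seed=2)
        status = simulate.assign_case_control(d, null, baseline_logit=0.0,
                                              seed=3)
        se = math.sqrt(0.25 / 5000)
        assert abs(status.mean() - 0.5) < 3 * se

    def test_saturating_effect_makes_carriers_cases(self):
        pool = HaplotypePool("s", [1], [
            Haplotype("A", 0.7, disease_log_or=0.0),
            Haplotype("G", 0.3, disease_log_or=10.0),
        ])
        d = simulate.sample_diplotypes(pool, 2000, seed=4)
        status = simulate.assign_case_control(d, pool, baseline_logit=0.0,
                                              seed=5)
        carriers = (d == 1).any(axis=1)
        assert status[carriers].mean() > 0.99

    def test_unknown_haplotype_rejected(self, pool_h11):
        d = np.array([[0, 7]])
        with pytest.raises(ValueError):
            simulate.assign_case_control(d, pool_h11)


class TestGenotypingNoise:
    def test_zero_rates_identity(self, small_cohort):
        _, g = small_cohort
        out = simulate.add_genotyping_noise(g, 0.0, 0.0, seed=0)
        np.testing.assert_array_equal(out, g)

    def test_missing_fraction_matches_rate(self, small_cohort):
        _, g = small_cohort
        out = simulate.add_genotyping_noise(g, 0.05, 0.0, seed=1)
        frac = (out == -1).mean()
        assert abs(frac - 0.05) < 0.01

    def test_errors_stay_valid_and_change_monomorphic_columns(self):
        g = np.zeros((500, 1), dtype=np.int8)
        out = simulate.add_genotyping_noise(g, 0.0, 0.2, seed=2)
        assert set(np.unique(out)) <= {0, 1, 2}
        assert (out == 1).sum() > 0  # column now polymorphic

    def test_het_errors_step_to_homozygotes(self):
        g = np.ones((2000, 1), dtype=np.int8)
        out = simulate.add_genotyping_noise(g, 0.0, 0.5, seed=3)
        assert {0, 2} <= set(np.unique(out))


class TestQuantTrait:
    def test_no_effect_no_noise_constant(self, pool_h11):
        flat = HaplotypePool("f", list(pool_h11.positions), [
            Haplotype(h.alleles, h.frequency, trait_effect=0.0)
            for h in pool_h11.haplotypes
        ])
        d = simulate.sample_diplotypes(flat, 100, seed=0)
        t = simulate.simulate_quant_trait(d, flat, None, noise_sd=0.0, seed=1)
        assert np.allclose(t, t[0])

    def test_noiseless_trait_is_affine_in_dosage(self, pool_h11):
        d = simulate.sample_diplotypes(pool_h11, 400, seed=6)
        t = simulate.simulate_quant_trait(d, pool_h11, None, noise_sd=0.0,
                                          seed=0)
        counts = simulate.haplotype_counts(d, 5)
        effects = np.array([h.trait_effect for h in pool_h11.haplotypes])
        np.testing.assert_allclose(t, counts @ effects)

    def test_misaligned_covariates_rejected(self, pool_h11):
        d = simulate.sample_diplotypes(pool_h11, 10, seed=0)
        with pytest.raises(ValueError):
            simulate.simulate_quant_trait(d, pool_h11,
                                          pd.DataFrame({"age": [1.0] * 5}))


class TestCopyNumber:
    def test_diploid_identity(self):
        pool = HaplotypePool("c", [1], [
            Haplotype("A", 0.5, copy_number_map={"gamma": 1}),
            Haplotype("G", 0.5, copy_number_map={"gamma": 1}),
        ])
        d = simulate.sample_diplotypes(pool, 50, seed=0)
        cn = simulate.simulate_copy_number(d, pool, noise_sd=0.0)
        assert (cn["gamma"] == 2.0).all()

    def test_homozygote_for_two_copy_haplotype_gets_four(self, pool_h11):
        k = next(i for i, h in enumerate(pool_h11.haplotypes)
                 if h.alleles == "GCCTG")
        d = np.full((10, 2), k)
        cn = simulate.simulate_copy_number(d, pool_h11, noise_sd=0.0)
        assert (cn["gamma"] == 4.0).all()

    def test_group_means_ordered_control_below_protective(self, pool_h11):
        rng_d = simulate.sample_diplotypes(pool_h11, 3000, seed=9)
        cn = simulate.simulate_copy_number(rng_d, pool_h11, noise_sd=0.3,
                                           seed=9)
        k = next(i for i, h in enumerate(pool_h11.haplotypes)
                 if h.alleles == "GCCTG")
        ref = pool_h11.haplotypes.index(pool_h11.reference())
        hom_prot = (rng_d == k).all(axis=1)
        hom_ref = (rng_d == ref).all(axis=1)
        assert cn.loc[hom_ref, "gamma"].mean() < cn.loc[hom_prot, "gamma"].mean()

    def test_missing_map_entry_rejected(self):
        pool = HaplotypePool("c", [1], [
            Haplotype("A", 0.5, copy_number_map={"gamma": 1}),
            Haplotype("G", 0.5, copy_number_map={}),
        ])
        d = simulate.sample_diplotypes(pool, 5, seed=0)
        with pytest.raises(ValueError):
            simulate.simulate_copy_number(d, pool)


class TestCohortAndRoundTrip:
    def test_genotypes_equal_haplotype_sum_before_noise(self, pool_h11):
        d = simulate.sample_diplotypes(pool_h11, 200, seed=3)
        g = simulate.genotypes_from_diplotypes(d, pool_h11)
        chroms = phased_chromosomes(d, pool_h11)
        expected = chroms[0::2] + chroms[1::2]
        np.testing.assert_array_equal(g, expected)

    def test_cohort_determinism(self, default_pools):
        spec = simulate.CohortSpec(n_individuals=200, seed=77,
                                   missing_rate=0.01)
        a = simulate.simulate_cohort(default_pools, spec)
        b = simulate.simulate_cohort(default_pools, spec)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.status, b.status)
        pd.testing.assert_frame_equal(a.traits, b.traits)

    def test_write_read_round_trip(self, default_pools, tmp_path):
        spec = simulate.CohortSpec(n_individuals=50, seed=8,
                                   missing_rate=0.05)
        cohort = simulate.simulate_cohort(default_pools, spec)
        paths = io.write_cohort(cohort, tmp_path / "cohort")
        variants, genotypes, samples = io.read_vcf(paths["vcf"])
        assert samples == cohort.sample_ids
        assert (variants["pos"].diff().dropna() >= 0).all()
        order = np.argsort(cohort.variants["pos"].to_numpy(), kind="stable")
        np.testing.assert_array_equal(genotypes, cohort.genotypes[:, order])
        pheno = io.read_pheno_tsv(paths["pheno"])
        np.testing.assert_array_equal(pheno["status"].to_numpy(),
                                      cohort.status)

    def test_empty_vcf_valid(self, tmp_path):
        variants = pd.DataFrame(columns=["chrom", "pos", "id", "ref", "alt"])
        io.write_vcf(tmp_path / "empty.vcf", variants,
                     np.empty((2, 0), dtype=np.int8), ["a", "b"])
        text = (tmp_path / "empty.vcf").read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert "#CHROM" in text

    def test_clade_coupling_tags_h2(self, default_pools):
        spec = simulate.CohortSpec(n_individuals=4000, seed=5)
        cohort = simulate.simulate_cohort(default_pools, spec,
                                          clade_coupling=True)
        tag = cohort.genotypes[:, cohort.variants["id"].tolist().index("h2_tag")]
        # HWE expectations at H2 frequency 0.2: 0.64 / 0.32 / 0.04
        fracs = np.bincount(tag, minlength=3) / len(tag)
        np.testing.assert_allclose(fracs, [0.64, 0.32, 0.04], atol=0.03)
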