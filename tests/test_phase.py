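"""Multi-marker EM phasing: closed-form cases, a simplex-grid likelihood
oracle, recovery from default pools, dosage identities, pruning, tag-SNP
clade calls."""

import itertools

import numpy as np
import pytest

from hapblock import phase, simulate

from conftest import phased_chromosomes, truth_codes


def simplex_oracle(genotypes, codes, step=0.02):
    """Exhaustive likelihood maximization over a coarse-to-fine grid on the
    haplotype frequency simplex (feasible for <= 4 haplotypes)."""
    genotypes = np.asarray(genotypes)
    H = len(codes)
    pair_lists = []
    for row in genotypes:
        pairs = phase._compatible_pairs(row)
        pairs = [(a, b) for a, b in pairs if a in codes and b in codes]
        pair_lists.append(pairs)
    idx = {c: k for k, c in enumerate(codes)}

    def loglik(f):
        ll = 0.0
        for pairs in pair_lists:
            lik = sum(f[idx[a]] * f[idx[b]] * (2 if a != b else 1)
                      for a, b in pairs)
            ll += np.log(max(lik, 1e-300))
        return ll

    best, best_ll = None, -np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for combo in itertools.product(ticks, repeat=H - 1):
        last = 1.0 - sum(combo)
        if last < -1e-9:
            continue
        f = np.array(list(combo) + [max(last, 0.0)])
        llv = loglik(f)
        if llv > best_ll:
            best_ll, best = llv, f
    # local refinement around the coarse optimum
    for _ in range(3):
        step /= 5
        center = best
        grids = [np.clip(center[k] + np.arange(-2, 3) * step, 0, 1)
                 for k in range(H - 1)]
        for combo in itertools.product(*grids):
            last = 1.0 - sum(combo)
            if last < -1e-9:
                continue
            f = np.array(list(combo) + [max(last, 0.0)])
            llv = loglik(f)
            if llv > best_ll:
                best_ll, best = llv, f
    return best


class TestEMFrequencies:
    def test_homozygotes_only_direct_counts(self):
        g = np.array([[0, 0, 0]] * 6 + [[2, 2, 2]] * 3 + [[0, 2, 0]] * 1)
        hs = phase.em_haplotype_freqs(g)
        est = dict(zip(hs.allele_strings(), hs.frequencies))
        assert est["000"] == pytest.approx(0.6)
        assert est["111"] == pytest.approx(0.3)
        assert est["010"] == pytest.approx(0.1)

    def test_three_snp_toy_matches_simplex_oracle(self):
        # anchoring homozygotes plus one double heterozygote
        g = np.array([[0, 0, 0]] * 4 + [[2, 2, 0]] * 2 + [[1, 1, 0]] * 3
                     + [[0, 0, 2]] * 1)
        hs = phase.em_haplotype_freqs(g, tol=1e-10, max_iter=2000)
        est = dict(zip(hs.haplotype_codes, hs.frequencies))
        codes = sorted(est)
        oracle = simplex_oracle(g, codes)
        for k, c in enumerate(codes):
            assert est[c] == pytest.approx(oracle[k], abs=1e-4)

    def test_default_pool_recovery(self, pool_h12):
        codes = truth_codes(pool_h12)
        for seed in range(3):
            d = simulate.sample_diplotypes(pool_h12, 2000, seed=seed)
            g = simulate.genotypes_from_diplotypes(d, pool_h12)
            hs = phase.em_haplotype_freqs(g, "H1.2")
            est = dict(zip(hs.allele_strings(), hs.frequencies))
            for h in pool_h12.haplotypes:
                assert abs(est.get(codes[h.alleles], 0.0)
                           - h.frequency) <= 0.02
            truth_set = set(codes.values())
            assert all(f <= 0.01 for s, f in est.items()
                       if s not in truth_set)

    def test_loglik_monotone(self, pool_h12):
        d = simulate.sample_diplotypes(pool_h12, 500, seed=50)
        g = simulate.genotypes_from_diplotypes(d, pool_h12)
        g = simulate.add_genotyping_noise(g, 0.05, 0.01, seed=51)
        hs = phase.em_haplotype_freqs(g, "H1.2")
        tr = hs.loglik_trace
        assert all(tr[k + 1] >= tr[k] - 1e-9 for k in range(len(tr) - 1))

    def test_all_missing_individual_excluded(self):
        g = np.array([[0, 1], [2, 0], [-1, -1], [1, 1]])
        hs = phase.em_haplotype_freqs(g)
        assert hs.excluded_samples == [2]
        dos = phase.haplotype_dosages(hs, n_samples=4)
        assert np.isnan(dos[2]).all()
        assert np.allclose(dos[[0, 1, 3]].sum(axis=1), 2.0)

    def test_too_many_markers_rejected(self):
        with pytest.raises(ValueError):
            phase.em_haplotype_freqs(np.zeros((4, 16), dtype=np.int8))

    def test_missing_sites_summed_over(self):
        # a single missing site in an otherwise unambiguous individual
        g = np.array([[0, 0]] * 8 + [[2, 2]] * 2 + [[-1, 0]] * 1)
        hs = phase.em_haplotype_freqs(g, tol=1e-10, max_iter=500)
        est = dict(zip(hs.allele_strings(), hs.frequencies))
        # the missing individual is most plausibly 00/00
        assert est["00"] > 0.7


class TestPosteriorsAndDosages:
    def test_unambiguous_individual_single_pair(self, pool_h12):
        g = np.array([[0] * 8, [2] * 8])
        hs = phase.em_haplotype_freqs(g)
        post = phase.diplotype_posteriors(hs, 0)
        assert len(post) == 1
        assert post["posterior"].iloc[0] == pytest.approx(1.0)

    def test_double_het_symmetric_split(self):
        # equal-frequency resolutions -> 0.5/0.5
        g = np.array([[0, 0]] * 5 + [[2, 2]] * 5 + [[0, 2]] * 5
                     + [[2, 0]] * 5 + [[1, 1]] * 2)
        hs = phase.em_haplotype_freqs(g, tol=1e-12, max_iter=5000)
        post = phase.diplotype_posteriors(hs, 20)
        probs = sorted(post["posterior"])
        assert probs == pytest.approx([0.5, 0.5], abs=1e-3)

    def test_posteriors_reproduce_m_step_counts(self, pool_h12):
        d = simulate.sample_diplotypes(pool_h12, 300, seed=52)
        g = simulate.genotypes_from_diplotypes(d, pool_h12)
        hs = phase.em_haplotype_freqs(g, tol=1e-10, max_iter=1000)
        # summing posterior haplotype counts over individuals reproduces the
        # M-step numerator: freqs * 2n
        acc = np.zeros(hs.n_haplotypes)
        for i in range(300):
            post = phase.diplotype_posteriors(hs, i)
            for _, row in post.iterrows():
                acc[int(row["h1"])] += row["posterior"]
                acc[int(row["h2"])] += row["posterior"]
        np.testing.assert_allclose(acc, 2 * 300 * hs.frequencies, atol=1e-6)

    def test_homozygote_dosage_two(self):
        g = np.array([[0, 0]] * 3 + [[2, 2]] * 2)
        hs = phase.em_haplotype_freqs(g)
        dos = phase.haplotype_dosages(hs)
        k00 = list(hs.allele_strings()).index("00")
        assert dos[0, k00] == pytest.approx(2.0)

    def test_mean_dosage_equals_twice_frequency(self, pool_h12):
        d = simulate.sample_diplotypes(pool_h12, 400, seed=53)
        g = simulate.genotypes_from_diplotypes(d, pool_h12)
        hs = phase.em_haplotype_freqs(g, tol=1e-12, max_iter=5000)
        dos = phase.haplotype_dosages(hs)
        np.testing.assert_allclose(dos.mean(axis=0), 2 * hs.frequencies,
                                   atol=1e-9)

    def test_dosages_correlate_with_truth(self, pool_h12):
        d = simulate.sample_diplotypes(pool_h12, 1000, seed=54)
        g = simulate.genotypes_from_diplotypes(d, pool_h12)
        hs = phase.em_haplotype_freqs(g, "H1.2")
        dos = phase.haplotype_dosages(hs)
        codes = truth_codes(pool_h12)
        strings = hs.allele_strings()
        true_counts = simulate.haplotype_counts(d, len(pool_h12.haplotypes))
        for k, h in enumerate(pool_h12.haplotypes):
            if h.frequency < 0.05:
                continue
            col = strings.index(codes[h.alleles])
            r = np.corrcoef(dos[:, col], true_counts[:, k])[0, 1]
            assert r > 0.99


class TestPruneAndLabels:
    def test_all_above_threshold_identity(self, pool_h11):
        d = simulate.sample_diplotypes(pool_h11, 800, seed=55)
        g = simulate.genotypes_from_diplotypes(d, pool_h11)
        hs = phase.em_haplotype_freqs(g, "H1.1")
        pruned = phase.prune_rare(hs, 0.01)
        truth = set(truth_codes(pool_h11).values())
        kept = [hs.allele_strings()[k] for k in phase.retained_indices(pruned)]
        assert truth <= set(kept)

    def test_boundary_frequency_kept_and_raw_scale_retained(self, pool_h12):
        d = simulate.sample_diplotypes(pool_h12, 5000, seed=56)
        g = simulate.genotypes_from_diplotypes(d, pool_h12)
        hs = phase.em_haplotype_freqs(g, "H1.2")
        pruned = phase.prune_rare(hs, 0.01)
        kept = phase.retained_indices(pruned)
        # frequencies are untouched (no renormalization)
        np.testing.assert_array_equal(pruned.frequencies, hs.frequencies)
        codes = truth_codes(pool_h12)
        strings = hs.allele_strings()
        rare = [codes["TTAAAATG"], codes["TTTCGACG"]]  # true freq 0.01
        kept_strings = {strings[k] for k in kept}
        present = [c for c in rare
                   if c in strings
                   and hs.frequencies[strings.index(c)] >= 0.01]
        for c in present:
            assert c in kept_strings

    def test_injected_rare_artifact_dropped(self):
        g = np.array([[0, 0]] * 99 + [[1, 1]] * 1)
        hs = phase.em_haplotype_freqs(g, tol=1e-10, max_iter=1000)
        pruned = phase.prune_rare(hs, 0.01)
        kept = phase.retained_indices(pruned)
        strings = [hs.allele_strings()[k] for k in kept]
        assert "00" in strings
        assert len(strings) < hs.n_haplotypes

    def test_all_pruned_rejected(self):
        g = np.array([[0, 0]] * 4 + [[2, 2]] * 4)
        hs = phase.em_haplotype_freqs(g)
        with pytest.raises(ValueError):
            phase.prune_rare(hs, 0.99)

    def test_labels_ranked_by_frequency(self):
        g = np.array([[0, 0]] * 6 + [[2, 2]] * 3 + [[0, 2]] * 1)
        hs = phase.em_haplotype_freqs(g, block_id="T")
        labels = dict(zip(hs.allele_strings(), hs.labels()))
        assert labels["00"] == "Ta"
        assert labels["11"] == "Tb"
        assert labels["01"] == "Tc"


class TestTagSNPClades:
    def test_all_reference_cohort(self):
        g = np.zeros((10, 3), dtype=np.int8)
        clades = phase.call_tag_snp_clades(g, 0)
        assert (clades == "H1/H1").all()

    def test_hwe_fractions_at_h2_freq(self):
        rng = np.random.default_rng(57)
        tag = ((rng.random(20_000) < 0.2).astype(np.int8)
               + (rng.random(20_000) < 0.2).astype(np.int8))
        clades = phase.call_tag_snp_clades(tag[:, None], 0)
        fracs = clades.value_counts(normalize=True)
        assert fracs["H1/H1"] == pytest.approx(0.64, abs=0.02)
        assert fracs["H1/H2"] == pytest.approx(0.32, abs=0.02)
        assert fracs["H2/H2"] == pytest.approx(0.04, abs=0.01)
        subset = phase.homozygote_subset(clades, "H1")
        assert len(subset) == (clades == "H1/H1").sum()

    def test_missing_tag_excluded(self):
        g = np.array([[0], [1], [-1], [2]], dtype=np.int8)
        clades = phase.call_tag_snp_clades(g, 0)
        assert clades.isna().sum() == 1
        assert 2 not in phase.homozygote_subset(clades, "H1")
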