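import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_gm
from pinpop import published
from pinpop.stats import (
    allelic_richness, fis, gene_diversity_hs, nucleotide_diversity,
    observed_heterozygosity, pairwise_fst, region_mean_fst, tajimas_d,
    watterson_theta, wc_fst,
)


class TestHeterozygosity:
    def test_mean_het_fraction_over_sites(self):
        # 3 sites x 4 individuals with 2, 1, 0 hets
        g = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0], [0, 0, 0]])
        gm = make_gm(g, pop_labels=["p"] * 4)
        assert observed_heterozygosity(gm, "p") == pytest.approx(0.25)

    def test_extremes(self):
        gm = make_gm(np.full((4, 3), 1), pop_labels=["p"] * 4)
        assert observed_heterozygosity(gm, "p") == 1.0
        gm = make_gm(np.full((4, 3), 2), pop_labels=["p"] * 4)
        assert observed_heterozygosity(gm, "p") == 0.0


class TestGeneDiversity:
    def test_two_opposite_homozygotes(self):
        gm = make_gm([[0], [2]], pop_labels=["p", "p"])
        assert gene_diversity_hs(gm, "p") == pytest.approx(1.0)

    def test_all_het_ten_individuals(self):
        gm = make_gm(np.ones((10, 1)), pop_labels=["p"] * 10)
        assert gene_diversity_hs(gm, "p") == pytest.approx(0.5)

    def test_monomorphic_site_contributes_zero(self):
        g = np.column_stack([np.zeros(10), np.ones(10)])
        gm = make_gm(g, pop_labels=["p"] * 10)
        assert gene_diversity_hs(gm, "p") == pytest.approx(0.25)


class TestFis:
    def test_consistent_with_ho_hs_ratio(self, small_dataset):
        gm = small_dataset.genotypes
        pop = gm.populations()[0]
        expected = 1 - (observed_heterozygosity(gm, pop)
                        / gene_diversity_hs(gm, pop))
        assert fis(gm, pop) == pytest.approx(expected)

    def test_all_het_gives_minus_one(self):
        gm = make_gm(np.ones((10, 1)), pop_labels=["p"] * 10)
        assert fis(gm, "p") == pytest.approx(-1.0)

    def test_no_hets_gives_plus_one(self):
        g = np.repeat([[0], [2]], 5, axis=0)
        gm = make_gm(g, pop_labels=["p"] * 10)
        assert fis(gm, "p") == pytest.approx(1.0)


class TestNucleotideDiversity:
    def test_monomorphic_zero(self):
        gm = make_gm(np.zeros((4, 5)), pop_labels=["p"] * 4)
        assert nucleotide_diversity(gm, "p", total_length=100) == 0.0

    def test_two_sequences_one_difference(self):
        gm = make_gm([[1]], pop_labels=["p"])  # one het = 2 chroms differing
        assert nucleotide_diversity(gm, "p", 100) == pytest.approx(0.01)

    def test_four_haplotypes_three_one_split(self):
        # alt counts (1 of 4 chromosomes), L = 10 -> 0.05
        gm = make_gm([[1], [0]], pop_labels=["p", "p"])
        assert nucleotide_diversity(gm, "p", 10) == pytest.approx(0.05)


class TestWatterson:
    def test_values(self):
        assert watterson_theta(0, 10) == 0.0
        assert watterson_theta(10, 10) == pytest.approx(10 / 2.8289682, rel=1e-6)
        assert watterson_theta(7, 2) == pytest.approx(7.0)

    def test_needs_two_chromosomes(self):
        with pytest.raises(ValueError):
            watterson_theta(5, 1)


class TestTajimasD:
    @staticmethod
    def _oracle(pi_total, s, n):
        """Direct transcription of the 1989 constants."""
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i ** 2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
        return (pi_total - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))

    def test_fixture_matches_bruteforce_constants(self):
        # n = 4 haplotypes (2 diploids), site patterns (1,0,0,0), (1,1,0,0)
        gm = make_gm([[1, 1], [0, 1]], pop_labels=["p", "p"])
        pi_total = (2 * 0.25 * 0.75 + 2 * 0.5 * 0.5) * 4 / 3
        assert tajimas_d(gm, "p") == pytest.approx(
            self._oracle(pi_total, 2, 4))

    def test_undefined_without_segregating_sites(self):
        gm = make_gm(np.zeros((4, 3)), pop_labels=["p"] * 4)
        with pytest.raises(ValueError):
            tajimas_d(gm, "p")

    def test_neutral_simulation_mean_near_zero(self):
        """Constant-size coalescent: E[D] is close to 0."""
        from pinpop.demography import DemographicModel, simulate_sfs_counts

        model = DemographicModel("DIV", n_smo=1000, n_chd=1000, t_div=1e-6,
                                 n_anc=1000)
        vals = []
        rng = np.random.default_rng(9)
        for rep in range(400):
            sfs, _ = simulate_sfs_counts(model, 9, 9, 30,
                                         seed=int(rng.integers(2 ** 31)),
                                         folded=False)
            counts = np.nonzero(sfs.counts)
            # rebuild a complete-data genotype matrix from allele counts
            sites = []
            for i, j, m in zip(*counts, sfs.counts[counts]):
                k = i + j
                for _ in range(int(m)):
                    chroms = np.zeros(18, dtype=np.int8)
                    chroms[rng.permutation(18)[:k]] = 1
                    sites.append(chroms[0::2] + chroms[1::2])
            g = np.array(sites).T
            gm = make_gm(g, pop_labels=["p"] * 9)
            vals.append(tajimas_d(gm, "p"))
        assert abs(np.mean(vals)) < 0.1


class TestWcFst:
    @staticmethod
    def _oracle_site(pops_geno):
        """Scalar-loop Weir-Cockerham components for one site."""
        r = len(pops_geno)
        n = [len(g) for g in pops_geno]
        p = [sum(g) / (2 * len(g)) for g in pops_geno]
        h = [sum(1 for x in g if x == 1) / len(g) for g in pops_geno]
        nbar = sum(n) / r
        nc = (sum(n) - sum(x ** 2 for x in n) / sum(n)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
        a = (nbar / nc) * (s2 - 1 / (nbar - 1)
                           * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        return a, b, c

    def test_fixed_difference_gives_one(self):
        g = np.array([[0], [0], [0], [2], [2], [2]])
        gm = make_gm(g, pop_labels=["p1"] * 3 + ["p2"] * 3)
        assert wc_fst(gm, ["p1", "p2"]) == pytest.approx(1.0)

    def test_identical_populations_non_positive(self):
        block = np.array([[0], [1], [2]])
        gm = make_gm(np.vstack([block, block]),
                     pop_labels=["p1"] * 3 + ["p2"] * 3)
        assert wc_fst(gm, ["p1", "p2"]) <= 0.0

    def test_matches_independent_variance_component_oracle(self):
        g = np.array([[0], [0], [1], [1], [2], [2]])
        gm = make_gm(g, pop_labels=["p1"] * 3 + ["p2"] * 3)
        a, b, c = self._oracle_site([(0, 0, 1), (1, 2, 2)])
        assert wc_fst(gm, ["p1", "p2"]) == pytest.approx(
            a / (a + b + c), abs=1e-12)

    def test_multilocus_is_ratio_of_sums(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, rng.uniform(0.1, 0.9, size=6), size=(20, 6))
        gm = make_gm(g.astype(np.int8), pop_labels=["p1"] * 10 + ["p2"] * 10)
        num = den = 0.0
        for s in range(6):
            geno = [tuple(g[:10, s]), tuple(g[10:, s])]
            pbar = (sum(geno[0]) + sum(geno[1])) / 40
            if pbar in (0.0, 1.0):
                continue
            a, b, c = self._oracle_site(geno)
            num += a
            den += a + b + c
        assert wc_fst(gm, ["p1", "p2"]) == pytest.approx(num / den, abs=1e-12)

    def test_invariant_to_site_and_individual_order(self, small_dataset):
        gm = small_dataset.genotypes
        v1 = wc_fst(gm)
        rng = np.random.default_rng(1)
        gm2 = gm.take_sites(rng.permutation(gm.n_sites))
        gm3 = gm2.take_individuals(rng.permutation(gm.n_individuals))
        assert wc_fst(gm3) == pytest.approx(v1, abs=1e-12)

    @pytest.mark.parametrize("nm_total,tol", [(0.5, 0.15), (5.0, 0.25)])
    def test_island_model_expectation(self, nm_total, tol):
        """On many-deme island-model data the estimator approaches the
        classical equilibrium value 1/(1 + 4*N*m).

        That value is itself an infinite-island approximation, biased low
        by O(1/d) for d demes, so the comparison bands are loose.
        """
        msprime = pytest.importorskip("msprime")
        d, n_diploid, n_sampled = 12, 6, 6
        n_e = 1000.0
        demography = msprime.Demography.island_model(
            [n_e] * d, migration_rate=nm_total / n_e / (d - 1))
        blocks = []
        for rep in range(12):
            ts = msprime.sim_ancestry(
                samples={i: n_diploid for i in range(n_sampled)},
                demography=demography, sequence_length=5e4,
                recombination_rate=1e-8, random_seed=100 + rep)
            ts = msprime.sim_mutations(ts, rate=1e-8,
                                       random_seed=1099 + rep)
            g = ts.genotype_matrix()
            blocks.append(np.minimum((g[:, 0::2] + g[:, 1::2]).T, 2))
        geno = np.concatenate(blocks, axis=1).astype(np.int8)
        pops = [f"p{i // n_diploid}" for i in range(geno.shape[0])]
        gm = make_gm(geno, pop_labels=pops)
        expected = 1 / (1 + 4 * nm_total)
        assert wc_fst(gm) == pytest.approx(expected, rel=tol)


class TestRegionMeans:
    def test_published_blocks(self):
        table = published.pairwise_fst_table()
        means = region_mean_fst(table, published.POPULATION_REGION)
        assert means["within_SMO"] == pytest.approx(0.0144, abs=5e-5)
        # printed as 0.012 (three decimals): compare at printed precision
        assert means["within_ChD"] == pytest.approx(0.012, abs=5e-4)
        assert means["between"] == pytest.approx(0.0536, abs=5e-5)

    def test_label_permutation_approaches_global_mean(self):
        table = published.pairwise_fst_table()
        tri = table.values[np.triu_indices(10, 1)]
        global_mean = tri.mean()
        rng = np.random.default_rng(3)
        within = []
        for _ in range(200):
            perm = rng.permutation(published.POPULATIONS)
            grouping = {p: ("SMO" if i < 5 else "ChD")
                        for i, p in enumerate(perm)}
            m = region_mean_fst(table, grouping)
            within.append((m["within_SMO"] + m["within_ChD"]) / 2)
        assert np.mean(within) == pytest.approx(global_mean, rel=0.02)

    def test_region_with_single_population_undefined(self):
        table = published.pairwise_fst_table()
        grouping = {p: "ChD" for p in published.POPULATIONS}
        grouping["Tolantongo"] = "SMO"
        means = region_mean_fst(table, grouping)
        assert math.isnan(means["within_SMO"])


class TestAllelicRichness:
    def test_monomorphic_and_rarefaction_one(self):
        gm = make_gm(np.zeros((5, 1)), pop_labels=["p"] * 5)
        assert allelic_richness(gm, "p", 2) == pytest.approx(1.0)
        gm = make_gm([[1], [1], [0], [2], [1]], pop_labels=["p"] * 5)
        assert allelic_richness(gm, "p", 1) == pytest.approx(1.0)

    def test_balanced_site_pair_subsample(self):
        # allele counts (5, 5), subsample of 2: 1 + (1 - 2*C(5,2)/C(10,2))
        g = [[1], [1], [1], [0], [2]]
        gm = make_gm(g, pop_labels=["p"] * 5)
        expected = 1 + (1 - 2 * math.comb(5, 2) / math.comb(10, 2))
        assert allelic_richness(gm, "p", 2) == pytest.approx(expected)


def test_pairwise_matrix_symmetric_with_zero_diagonal(small_dataset):
    fst = pairwise_fst(small_dataset.genotypes)
    assert np.allclose(fst.values, fst.values.T, equal_nan=True)
    assert np.allclose(np.diag(fst.values), 0.0)
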