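"""Diversity and differentiation statistics."""

import numpy as np
import pytest

from invadibe import popgen
from invadibe.genotype_io import GenotypeMatrix
from invadibe.simulate import SimParams, simulate_dataset

from _oracles import pair_theta_oracle, wc_theta_oracle


def matrix_from(dos, miss=None):
    dos = np.asarray(dos, dtype=np.int8)
    if miss is None:
        miss = np.zeros_like(dos, dtype=bool)
    return GenotypeMatrix([f"s{i}" for i in range(dos.shape[0])],
                          [f"L{j}" for j in range(dos.shape[1])], dos, miss)


class TestDiversity:
    def test_pi_hand_computed_single_locus(self):
        # two diploids with dosages (0, 2): p = 0.5, n = 4 copies
        G = matrix_from([[0], [2]])
        pi, se = popgen.nucleotide_diversity(G, G.sample_ids)
        assert pi == pytest.approx(4.0 / 3.0 * 0.5, abs=1e-12)

    def test_monomorphic_locus_contributes_zero(self):
        G = matrix_from([[0, 0], [0, 2]])
        pi, _ = popgen.nucleotide_diversity(G, G.sample_ids)
        assert pi == pytest.approx((0.0 + 4.0 / 3.0 * 0.5) / 2, abs=1e-12)

    def test_group_of_one_rejected(self):
        G = matrix_from([[0], [2]])
        with pytest.raises(ValueError):
            popgen.nucleotide_diversity(G, ["s0"])

    def test_heterozygosity_extremes(self):
        G = matrix_from([[0, 1], [2, 1]])           # locus 0 p=0.5 all hom,
        he, ho = popgen.heterozygosity(G, G.sample_ids)  # locus 1 all het
        assert he == pytest.approx(0.5, abs=1e-12)  # both loci at p=0.5
        assert ho == pytest.approx(0.5, abs=1e-12)  # (0 + 1)/2

    def test_pct_polymorphic(self):
        G = matrix_from([[0, 0, 1], [0, 2, 1]])
        assert popgen.pct_polymorphic(G, G.sample_ids) == pytest.approx(200 / 3)


class TestFis:
    def test_hwe_counts_near_zero(self):
        # 25/50/25 genotype counts at every locus -> f ~ 0 at large n
        block = np.repeat([0, 1, 2], [25, 50, 25])
        dos = np.tile(block[:, None], (1, 20))
        G = matrix_from(dos)
        est, (lo, hi) = popgen.fis(G, G.sample_ids, n_boot=99, seed=0)
        assert abs(est) < 0.01
        assert lo <= hi

    def test_all_heterozygotes_boundary(self):
        dos = np.ones((20, 10), dtype=np.int8)
        G = matrix_from(dos)
        est, _ = popgen.fis(G, G.sample_ids, n_boot=49, seed=0)
        assert est == pytest.approx(-1.0, abs=1e-12)

    def test_monomorphic_returns_nan(self):
        G = matrix_from(np.zeros((5, 4)))
        est, ci = popgen.fis(G, G.sample_ids, n_boot=9, seed=0)
        assert np.isnan(est)

    def test_agrees_in_sign_with_simple_estimator(self):
        rng = np.random.default_rng(2)
        # heterozygote-deficient genotypes (inbreeding-like)
        p = rng.uniform(0.2, 0.8, 200)
        f_true = 0.2
        probs = np.stack([(1 - p) ** 2 + f_true * p * (1 - p),
                          2 * p * (1 - p) * (1 - f_true),
                          p ** 2 + f_true * p * (1 - p)])
        dos = np.stack([rng.choice(3, size=200, p=probs[:, l] / probs[:, l].sum())
                        for l in range(200)]).T
        G = matrix_from(dos[:50])
        est, _ = popgen.fis(G, G.sample_ids, n_boot=49, seed=1)
        simple = popgen.fis_simple(G, G.sample_ids)
        assert est == pytest.approx(f_true, abs=0.1)
        assert simple == pytest.approx(est, abs=0.05)


class TestPrivateAlleles:
    def test_identical_fixed_groups_have_none(self):
        G = matrix_from([[0, 2], [0, 2], [0, 2], [0, 2]])
        counts = popgen.private_alleles(
            G, {"A": ["s0", "s1"], "B": ["s2", "s3"]})
        assert counts == {"A": 0, "B": 0}

    def test_planted_private_alleles_recovered(self):
        rng = np.random.default_rng(7)
        n, L = 10, 60
        dos = rng.binomial(2, 0.5, (n, L)).astype(np.int8)
        # plant: group A carries ALT privately at 12 loci where B is REF-fixed
        dos[:, :12] = 0
        dos[0, :12] = 1
        # make sure REF is present in both groups at those loci (A has 0s too)
        G = matrix_from(dos)
        groups = {"A": G.sample_ids[:5], "B": G.sample_ids[5:]}
        counts = popgen.private_alleles(G, groups)
        # count private alleles at the planted block only
        base = popgen.private_alleles(
            matrix_from(dos[:, 12:]), groups)
        assert counts["A"] - base["A"] == 12


class TestWcFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.5, (200, 100)).astype(np.int8)
        G = matrix_from(dos)
        res = popgen.wc_fst(G, G.sample_ids[:100], G.sample_ids[100:],
                            n_boot=0, n_perm=0)
        assert abs(res.theta) < 0.01

    def test_reciprocally_fixed_is_one(self):
        dos = np.vstack([np.zeros((3, 5)), np.full((3, 5), 2)])
        G = matrix_from(dos)
        res = popgen.wc_fst(G, G.sample_ids[:3], G.sample_ids[3:],
                            n_boot=0, n_perm=0)
        assert res.theta == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_equation_level_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, L = 6, 8
        dos = rng.integers(0, 3, (n, L))
        miss = rng.random((n, L)) < 0.15
        G = matrix_from(dos, miss)
        res = popgen.wc_fst(G, G.sample_ids[:3], G.sample_ids[3:],
                            n_boot=0, n_perm=0)
        assert res.theta == pytest.approx(
            wc_theta_oracle(dos, miss, [0, 0, 0, 1, 1, 1]), abs=1e-12)

    def test_relabeling_within_groups_invariant(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, (10, 40))
        G = matrix_from(dos)
        a, b = G.sample_ids[:5], G.sample_ids[5:]
        r1 = popgen.wc_fst(G, a, b, n_boot=0, n_perm=0).theta
        r2 = popgen.wc_fst(G, a[::-1], b[::-1], n_boot=0, n_perm=0).theta
        assert r1 == pytest.approx(r2, abs=1e-15)

    def test_ci_width_shrinks_with_more_loci(self):
        widths = []
        for L in (50, 800):
            rng = np.random.default_rng(9)
            sim = simulate_dataset(SimParams(n_per_cluster=(12, 12), n_loci=L,
                                             f_div=0.1, f_deme=0.0,
                                             missing_rate=0.0, seed=9))
            G = sim.genotypes
            res = popgen.wc_fst(G, G.sample_ids[:12], G.sample_ids[12:],
                                n_boot=199, n_perm=0, seed=1)
            widths.append(res.ci95[1] - res.ci95[0])
        assert widths[1] < widths[0]

    def test_no_shared_loci_raises(self):
        miss = np.array([[False, True], [False, True],
                         [True, False], [True, False]])
        G = matrix_from(np.ones((4, 2)), miss)
        with pytest.raises(ValueError, match="informative"):
            popgen.wc_fst(G, G.sample_ids[:2], G.sample_ids[2:],
                          n_boot=0, n_perm=0)

    def test_permutation_detects_structure(self):
        sim = simulate_dataset(SimParams(n_per_cluster=(15, 15), n_loci=300,
                                         f_div=0.15, f_deme=0.0, seed=4))
        G = sim.genotypes
        res = popgen.wc_fst(G, G.sample_ids[:15], G.sample_ids[15:],
                            n_boot=0, n_perm=199, seed=5)
        assert res.perm_p == pytest.approx(1 / 200)


class TestPairwiseFst:
    def test_identical_and_opposite_genotypes(self):
        G = matrix_from([[0, 0, 0], [0, 0, 0], [2, 2, 2]])
        m = popgen.pairwise_individual_fst(G)
        assert m[0, 1] <= 0 or np.isnan(m[0, 1])  # identical: <=0 (or 0/0)
        assert m[0, 2] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dos = rng.integers(0, 3, (4, 30))
        miss = rng.random((4, 30)) < 0.1
        G = matrix_from(dos, miss)
        m = popgen.pairwise_individual_fst(G)
        for i in range(4):
            for j in range(i + 1, 4):
                expect = pair_theta_oracle(dos[i], dos[j], ~miss[i], ~miss[j])
                if np.isnan(expect):
                    assert np.isnan(m[i, j])
                else:
                    assert m[i, j] == pytest.approx(expect, abs=1e-12)
        assert np.allclose(m, m.T, equal_nan=True)


class TestPDistance:
    def test_identical_sequences(self):
        G = matrix_from([[0, 2, 1], [0, 2, 1]])
        # ignore: the het site is excluded -> 0/2
        assert popgen.p_distance_matrix(G, "ignore")[0, 1] == 0.0
        # average: het vs het contributes expected mismatch 0.5 over 3 sites
        assert popgen.p_distance_matrix(G, "average")[0, 1] == pytest.approx(
            0.5 / 3)
        G2 = matrix_from([[0, 2], [0, 2]])
        assert popgen.p_distance_matrix(G2, "average")[0, 1] == 0.0

    def test_one_of_four_sites_differs(self):
        G = matrix_from([[0, 0, 0, 0], [0, 0, 0, 2]])
        assert popgen.p_distance_matrix(G, "ignore")[0, 1] == pytest.approx(0.25)

    def test_het_vs_hom_contributes_half_in_average_mode(self):
        G = matrix_from([[1], [0]])     # R vs A at an A/G site
        assert np.isnan(popgen.p_distance_matrix(G, "ignore")[0, 1])
        assert popgen.p_distance_matrix(G, "average")[0, 1] == pytest.approx(0.5)

    def test_ignore_equals_hamming_on_hom_only(self):
        rng = np.random.default_rng(1)
        dos = 2 * rng.integers(0, 2, (5, 40))
        G = matrix_from(dos)
        m = popgen.p_distance_matrix(G, "ignore")
        assert m.min() >= 0 and np.allclose(m, m.T)
        expect = (dos[0] != dos[1]).mean()
        assert m[0, 1] == pytest.approx(expect)
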