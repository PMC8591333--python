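"""Diversity statistics, Weir & Cockerham theta, and AMOVA."""

import numpy as np
import pytest

from demohist import (
    amova,
    diversity_table,
    expected_heterozygosity,
    fixation_indices,
    fst_matrix,
    nucleotide_diversity,
    observed_heterozygosity,
    pairwise_fst,
)
from demohist.diversity import UndefinedStatisticError
from demohist.genotypes import MISSING

from conftest import make_matrix


class TestHeterozygosity:
    def test_observed_all_homozygous_is_zero(self):
        g = make_matrix([[0, 2], [2, 0], [0, 0]])
        assert observed_heterozygosity(g, [0, 1, 2]) == 0.0

    def test_observed_all_heterozygous_is_one(self):
        g = make_matrix([[1, 1], [1, 1]])
        assert observed_heterozygosity(g, [0, 1]) == 1.0

    def test_observed_hand_example(self):
        # 4 individuals, 2 loci: heterozygote fractions 3/4 and 1/4
        g = make_matrix([[0, 1], [1, 1], [2, 0], [1, 2]])
        assert observed_heterozygosity(g, [0, 1, 2, 3]) == pytest.approx(0.5)

    def test_expected_monomorphic_is_zero(self):
        g = make_matrix([[0], [0], [0]])
        assert expected_heterozygosity(g, [0, 1, 2]) == 0.0

    def test_expected_unbiased_correction_at_half(self):
        # p = 0.5 in 10 diploids: (2n/(2n-1)) * 0.5 = 10/19
        g = make_matrix([[1]] * 10)
        assert expected_heterozygosity(g, range(10)) == pytest.approx(20 / 19 * 0.5)

    def test_expected_single_heterozygote_small_sample(self):
        # n = 1 diploid: correction 2n/(2n-1) = 2 applied to 0.5
        g = make_matrix([[1]])
        assert expected_heterozygosity(g, [0]) == pytest.approx(1.0)

    def test_all_missing_population_raises(self):
        g = make_matrix([[MISSING], [0]])
        with pytest.raises(UndefinedStatisticError):
            observed_heterozygosity(g, [0])


class TestNucleotideDiversity:
    def test_monomorphic_is_zero(self):
        g = make_matrix([[0], [0]])
        assert nucleotide_diversity(g, [0, 1]) == 0.0

    def test_pairwise_difference_enumeration(self):
        # k = 4 alleles, j = 2 alternates: 2*2*2/(4*3) = 2/3
        g = make_matrix([[1], [1]])
        assert nucleotide_diversity(g, [0, 1]) == pytest.approx(2 / 3)

    def test_mean_over_loci(self):
        # loci with j/k = 1/4 and 2/4 -> mean(1/2, 2/3)
        g = make_matrix([[1, 1], [0, 1]])
        assert nucleotide_diversity(g, [0, 1]) == pytest.approx((0.5 + 2 / 3) / 2)


def wc_theta_oracle(counts_a, counts_b):
    """Single-locus Weir & Cockerham theta via the original per-population
    sums (independent route: explicit loops, no shared code)."""
    pops = [counts_a, counts_b]
    r = 2
    ns = [sum(c) for c in pops]  # diploid sample sizes
    ps = [(c[1] + 2 * c[2]) / (2 * n) for c, n in zip(pops, ns)]
    hs = [c[1] / n for c, n in zip(pops, ns)]
    nbar = sum(ns) / r
    nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestPairwiseFst:
    def test_fixed_difference_is_one(self):
        g = make_matrix([[0, 0], [0, 0], [2, 2], [2, 2]])
        assert pairwise_fst(g, [0, 1], [2, 3]) == pytest.approx(1.0)

    def test_identical_populations_not_positive(self):
        g = make_matrix([[0, 1], [1, 2], [2, 0], [0, 1], [1, 2], [2, 0]])
        assert pairwise_fst(g, [0, 1, 2], [3, 4, 5]) <= 1e-12

    def test_single_locus_matches_independent_oracle(self):
        # pop A: genotypes (1,1,1,0); pop B: (0,0,1,1)
        g = make_matrix([[1], [1], [1], [0], [0], [0], [1], [1]])
        got = pairwise_fst(g, [0, 1, 2, 3], [4, 5, 6, 7])
        a, b, c = wc_theta_oracle([1, 3, 0], [2, 2, 0])
        assert got == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_multilocus_ratio_of_sums(self):
        # per-locus genotype tallies as (n_hom_ref, n_het, n_hom_alt)
        rows_a = [[1, 1], [2, 2], [2, 1]]
        rows_b = [[0, 1], [0, 2], [1, 2]]
        g = make_matrix(rows_a + rows_b)
        got = pairwise_fst(g, [0, 1, 2], [3, 4, 5])
        num = den = 0.0
        for ca, cb in [((0, 1, 2), (2, 1, 0)), ((0, 2, 1), (0, 1, 2))]:
            a, b, c = wc_theta_oracle(list(ca), list(cb))
            num += a
            den += a + b + c
        assert got == pytest.approx(num / den, abs=1e-12)

    def test_no_shared_locus_raises(self):
        g = make_matrix([[0], [MISSING], [MISSING], [2]])
        with pytest.raises(UndefinedStatisticError):
            pairwise_fst(g, [0, 1], [2, 3])

    def test_fst_matrix_symmetric(self, amova_toy):
        g, pm = amova_toy
        m = fst_matrix(g, pm)
        np.testing.assert_allclose(m.values, m.values.T)
        assert (np.diag(m.values) == 0).all()


class TestFixationIndices:
    def test_reported_global_components(self):
        # variance components of the study system's hierarchical AMOVA
        fct, fsc, fst = fixation_indices(37.06608, 0.89979, 0.53215)
        assert round(fct, 4) == 0.9628
        assert round(fsc, 4) == 0.6284
        assert round(fst, 4) == 0.9862

    def test_degenerate_all_within(self):
        assert fixation_indices(0, 0, 1) == pytest.approx((0.0, 0.0, 0.0))

    def test_symmetric_half(self):
        assert fixation_indices(1, 0, 1) == pytest.approx((0.5, 0.0, 0.5))

    def test_identity_holds(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            sa, sb, sc = rng.uniform(0.01, 5, size=3)
            fct, fsc, fst = fixation_indices(sa, sb, sc)
            assert fst == pytest.approx(fct + (1 - fct) * fsc, abs=1e-9)

    def test_undefined_cases(self):
        with pytest.raises(UndefinedStatisticError):
            fixation_indices(1.0, 0.0, 0.0)
        with pytest.raises(UndefinedStatisticError):
            fixation_indices(0.0, 0.0, 0.0)


def balanced_amova_oracle(X, pops, groups):
    """Closed-form balanced-design AMOVA via centroid sums of squares.

    Independent route: Euclidean identities on dosage vectors instead of
    pairwise distances, and the balanced expected-mean-square
    coefficients (n, n, n*P/G).
    """
    X = np.asarray(X, dtype=float)
    pops = np.asarray(pops)
    groups = np.asarray(groups)
    N = len(X)
    P = len(np.unique(pops))
    G = len(np.unique(groups))
    n = N // P

    def ss_around(labels):
        ss = 0.0
        for lab in np.unique(labels):
            sub = X[labels == lab]
            ss += ((sub - sub.mean(axis=0)) ** 2).sum()
        return ss

    ss_wp = ss_around(pops)
    ss_wg = ss_around(groups)
    ss_tot = ((X - X.mean(axis=0)) ** 2).sum()
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_tot - ss_wg
    ms_wp = ss_wp / (N - P)
    ms_ap = ss_ap / (P - G)
    ms_ag = ss_ag / (G - 1)
    sc = ms_wp
    sb = (ms_ap - sc) / n
    sa = (ms_ag - sc - n * sb) / (n * P / G)
    return (ss_ag, ss_ap, ss_wp), (sa, sb, sc)


class TestAmova:
    def test_components_match_balanced_oracle(self, amova_toy):
        g, pm = amova_toy
        res = amova(g, pm, n_perm=0)
        pops = [pm.individual_to_population[i] for i in g.individual_ids]
        grps = [pm.population_to_group[p] for p in pops]
        (ss_ag, ss_ap, ss_wp), (sa, sb, sc) = balanced_amova_oracle(
            g.genotypes, pops, grps
        )
        lv = res.LEVELS
        assert res.ss[lv[0]] == pytest.approx(ss_ag, abs=1e-9)
        assert res.ss[lv[1]] == pytest.approx(ss_ap, abs=1e-9)
        assert res.ss[lv[2]] == pytest.approx(ss_wp, abs=1e-9)
        assert res.sigma2[lv[0]] == pytest.approx(sa, abs=1e-9)
        assert res.sigma2[lv[1]] == pytest.approx(sb, abs=1e-9)
        assert res.sigma2[lv[2]] == pytest.approx(sc, abs=1e-9)

    def test_df_and_percentages(self, amova_toy):
        g, pm = amova_toy
        res = amova(g, pm, n_perm=0)
        assert list(res.df.values()) == [1, 2, 8]  # G-1, P-G, N-P
        assert sum(res.df.values()) == g.n_individuals - 1
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(res.sigma2.values()) == pytest.approx(
            res.table().loc["total", "variance_component"]
        )

    def test_two_max_distinct_populations(self):
        # two groups of one population each, near-identical within, maximally
        # distinct between: all variance among groups (Fct -> 1, Fsc = 0)
        rows = [[0] * 4 for _ in range(4)] + [[2] * 4 for _ in range(4)]
        rows[0] = [1, 0, 0, 0]  # minimal within-population variation
        g = make_matrix(rows)
        from demohist import PopulationMap

        pm = PopulationMap(
            {f"ind{i}": ("P1" if i < 4 else "P2") for i in range(8)},
            {"P1": "A", "P2": "B"},
        )
        res = amova(g, pm, n_perm=0)
        assert res.fct > 0.97
        assert res.fsc == pytest.approx(0.0, abs=1e-12)

    def test_permutation_p_values_seeded_and_bounded(self, amova_toy):
        g, pm = amova_toy
        r1 = amova(g, pm, n_perm=99, seed=11)
        r2 = amova(g, pm, n_perm=99, seed=11)
        assert r1.p_values == r2.p_values
        for v in r1.p_values.values():
            assert 1 / 100 <= v <= 1.0
        # strong structure: among-population permutations should be extreme
        assert r1.p_values["fst"] == pytest.approx(1 / 100)

    def test_missingness_pairwise_deletion_runs(self, amova_toy):
        g, pm = amova_toy
        g.genotypes[0, 0] = MISSING
        res = amova(g, pm, n_perm=0)
        assert np.isfinite(res.fst)

    def test_identical_everything_raises(self):
        from demohist import PopulationMap

        g = make_matrix([[1, 1]] * 6)
        pm = PopulationMap(
            {f"ind{i}": ("P1" if i < 3 else "P2") for i in range(6)},
            {"P1": "A", "P2": "B"},
        )
        with pytest.raises(UndefinedStatisticError):
            amova(g, pm, n_perm=0)


class TestDiversityTable:
    def test_columns_and_values(self, amova_toy):
        g, pm = amova_toy
        tab = diversity_table(g, pm)
        assert list(tab.columns) == ["group", "n", "He", "Ho", "Pi"]
        assert (tab["n"] == 3).all()
        p1 = [i for i, ind in enumerate(g.individual_ids)
              if pm.individual_to_population[ind] == "P1"]
        assert tab.loc["P1", "Ho"] == pytest.approx(observed_heterozygosity(g, p1))
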