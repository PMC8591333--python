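"""Folded joint SFS construction, projection, folding, serialization."""

import itertools

import numpy as np
import pytest

from demohist import (
    FoldedJointSFS,
    PopulationMap,
    build_folded_joint_sfs,
    project_sfs,
    read_sfs,
    sfs_total,
    write_sfs,
)
from demohist.genotypes import MISSING
from demohist.sfs import SFSError, canonical_mask, fold_unfolded

from conftest import make_matrix


def two_group_map(n_a, n_b):
    inds = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    pm = PopulationMap(
        {ind: ("PA" if ind.startswith("a") else "PB") for ind in inds},
        {"PA": "GA", "PB": "GB"},
    )
    return inds, pm


class TestFolding:
    def test_single_minor_variant(self):
        inds, pm = two_group_map(2, 2)
        g = make_matrix([[1], [0], [0], [0]], individual_ids=inds)
        s = build_folded_joint_sfs(g, pm, "GA", "GB", (4, 4))
        assert s.counts[1, 0] == pytest.approx(1.0)
        assert sfs_total(s) == pytest.approx(1.0)

    def test_exact_half_frequency_split_between_conjugates(self):
        # alt counts (1, 3) of (4, 4): overall frequency exactly 1/2
        inds, pm = two_group_map(2, 2)
        g = make_matrix([[1], [0], [2], [1]], individual_ids=inds)
        s = build_folded_joint_sfs(g, pm, "GA", "GB", (4, 4))
        assert s.counts[1, 3] == pytest.approx(0.5)
        assert s.counts[3, 1] == pytest.approx(0.5)
        assert sfs_total(s) == pytest.approx(1.0)

    def test_self_conjugate_tie_keeps_unit_mass(self):
        inds, pm = two_group_map(2, 2)
        g = make_matrix([[1], [1], [2], [0]], individual_ids=inds)  # (2, 2) of (4, 4)
        s = build_folded_joint_sfs(g, pm, "GA", "GB", (4, 4))
        assert s.counts[2, 2] == pytest.approx(1.0)

    def test_fold_conserves_total_mass(self):
        rng = np.random.default_rng(3)
        u = rng.random((7, 5))
        f = fold_unfolded(u)
        assert f.sum() == pytest.approx(u.sum())
        mask = canonical_mask(6, 4)
        structural = mask.copy()
        structural[0, 0] = structural[6, 4] = False
        assert np.allclose(f[structural], 0.0)

    def test_mass_beyond_fold_rejected(self):
        counts = np.zeros((5, 5))
        counts[4, 3] = 1.0  # i + j > (n1+n2)/2
        with pytest.raises(SFSError, match="fold"):
            FoldedJointSFS(counts=counts, n1=4, n2=4)


def brute_force_projected_sfs(genotypes, group_sizes, n1, n2):
    """Exhaustive enumeration over all allele subsamples of each locus.

    Alleles are materialized as explicit 0/1 lists; every combination of
    n1 (resp. n2) alleles is enumerated and the folded configuration of
    each is averaged.  Independent of the hypergeometric code path.
    """
    na, nb = group_sizes
    counts = np.zeros((n1 + 1, n2 + 1))
    S = n1 + n2
    for locus in np.asarray(genotypes).T:
        alleles_a, alleles_b = [], []
        for i, gt in enumerate(locus):
            if gt == MISSING:
                continue
            target = alleles_a if i < na else alleles_b
            target.extend([1] * gt + [0] * (2 - gt))
        if len(alleles_a) < n1 or len(alleles_b) < n2:
            continue
        combos_a = list(itertools.combinations(range(len(alleles_a)), n1))
        combos_b = list(itertools.combinations(range(len(alleles_b)), n2))
        w = 1.0 / (len(combos_a) * len(combos_b))
        for ca in combos_a:
            i = sum(alleles_a[x] for x in ca)
            for cb in combos_b:
                j = sum(alleles_b[x] for x in cb)
                if 2 * (i + j) < S:
                    counts[i, j] += w
                elif 2 * (i + j) > S:
                    counts[n1 - i, n2 - j] += w
                else:
                    counts[i, j] += w / 2
                    counts[n1 - i, n2 - j] += w / 2
    return counts


class TestBuildWithProjection:
    def test_six_snp_fixture_matches_exhaustive_subsampling(self):
        inds, pm = two_group_map(3, 3)
        genotypes = [
            [0, 1, 2, 1, 0, 1],
            [1, 0, 2, 0, 0, 1],
            [0, 0, 1, MISSING, 1, 0],
            [0, 2, 0, 1, 2, 0],
            [1, 1, 0, 0, 2, 0],
            [0, 0, 1, 1, 1, 0],
        ]
        g = make_matrix(genotypes, individual_ids=inds)
        s = build_folded_joint_sfs(g, pm, "GA", "GB", (4, 4))
        oracle = brute_force_projected_sfs(genotypes, (3, 3), 4, 4)
        np.testing.assert_allclose(s.counts[~s.mask], oracle[~s.mask], atol=1e-12)
        assert sfs_total(s) == pytest.approx(oracle[~s.mask].sum())

    def test_full_projection_no_missing_equals_direct_counting(self):
        rng = np.random.default_rng(11)
        inds, pm = two_group_map(4, 3)
        genotypes = rng.integers(0, 3, size=(7, 40))
        g = make_matrix(genotypes, individual_ids=inds)
        s = build_folded_joint_sfs(g, pm, "GA", "GB", (8, 6))
        direct = np.zeros((9, 7))
        for locus in genotypes.T:
            i, j = locus[:4].sum(), locus[4:].sum()
            if 2 * (i + j) < 14:
                direct[i, j] += 1
            elif 2 * (i + j) > 14:
                direct[8 - i, 6 - j] += 1
            else:
                direct[i, j] += 0.5
                direct[8 - i, 6 - j] += 0.5
        np.testing.assert_allclose(s.counts, direct, atol=1e-9)

    def test_projection_too_large_everywhere_raises(self):
        inds, pm = two_group_map(2, 2)
        g = make_matrix([[1, 1], [MISSING, MISSING], [0, 1], [1, 0]], individual_ids=inds)
        with pytest.raises(SFSError, match="projection"):
            build_folded_joint_sfs(g, pm, "GA", "GB", (4, 4))


class TestProjectSFS:
    def one_entry_sfs(self):
        counts = np.zeros((5, 5))
        counts[1, 2] = 1.0
        return FoldedJointSFS(counts=counts, n1=4, n2=4)

    def test_projection_to_same_size_is_identity(self):
        s = self.one_entry_sfs()
        p = project_sfs(s, 4, 4)
        assert p.allclose(s)

    def test_hand_computed_hypergeometric_weights(self):
        # entry (1, 2) of (4, 4) projected to (2, 2):
        # deme 1: P(k of 2 | 1 of 4) = (1/2, 1/2, 0) for k=0,1,...
        # deme 2: P(l of 2 | 2 of 4) = (1/6, 4/6, 1/6)
        s = self.one_entry_sfs()
        p = project_sfs(s, 2, 2)
        unfolded = np.outer([1 / 2, 1 / 2, 0], [1 / 6, 4 / 6, 1 / 6])
        expected = fold_unfolded(unfolded)
        np.testing.assert_allclose(p.counts, expected, atol=1e-12)
        # monomorphic-corner mass is masked: total shrinks
        assert sfs_total(p) < sfs_total(s)

    def test_total_mass_non_increasing(self):
        rng = np.random.default_rng(5)
        counts = np.where(canonical_mask(6, 6), 0.0, rng.random((7, 7)))
        s = FoldedJointSFS(counts=counts, n1=6, n2=6)
        assert sfs_total(project_sfs(s, 4, 4)) <= sfs_total(s) + 1e-12

    def test_projection_commutes(self):
        rng = np.random.default_rng(9)
        counts = np.where(canonical_mask(8, 8), 0.0, rng.random((9, 9)))
        s = FoldedJointSFS(counts=counts, n1=8, n2=8)
        one_step = project_sfs(s, 4, 4)
        two_step = project_sfs(project_sfs(s, 6, 6), 4, 4)
        keep = ~one_step.mask  # masked monomorphic corners may differ
        np.testing.assert_allclose(one_step.counts[keep], two_step.counts[keep],
                                   atol=1e-9)

    def test_too_small_or_upward_projection_rejected(self):
        s = self.one_entry_sfs()
        with pytest.raises(SFSError):
            project_sfs(s, 1, 2)
        with pytest.raises(SFSError):
            project_sfs(s, 6, 6)


class TestSerialization:
    def make_sfs(self):
        rng = np.random.default_rng(2)
        counts = np.where(canonical_mask(4, 6), 0.0, rng.integers(0, 50, (5, 7)))
        return FoldedJointSFS(
            counts=counts.astype(float), n1=4, n2=6,
            total_sites=1000.0, mutation_rate=1e-7,
        )

    def test_fsc2_round_trip(self, tmp_path):
        s = self.make_sfs()
        path = write_sfs(s, tmp_path / "x.obs", format="fsc2")
        text = path.read_text()
        assert text.startswith("1 observations")
        assert "d0_0" in text and "d1_6" in text
        back = read_sfs(path)
        assert back.n1 == s.n1 and back.n2 == s.n2
        np.testing.assert_allclose(back.counts, s.counts)

    def test_tsv_round_trip_keeps_metadata(self, tmp_path):
        s = self.make_sfs()
        back = read_sfs(write_sfs(s, tmp_path / "x.tsv", format="tsv"))
        assert back.allclose(s)
        assert back.total_sites == s.total_sites
        assert back.mutation_rate == s.mutation_rate

    def test_empty_sfs_total_zero(self):
        s = FoldedJointSFS(counts=np.zeros((5, 5)), n1=4, n2=4)
        assert sfs_total(s) == 0.0
        with pytest.raises(SFSError):
            s.normalized()

    def test_masking_monomorphic_only(self):
        mask = canonical_mask(4, 4)
        assert mask[0, 0] and mask[4, 4]
        assert not mask[1, 0] and not mask[2, 2]
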