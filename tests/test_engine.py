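"""Coalescent engine checks against closed forms and the reference
structured-coalescent implementation."""

import numpy as np
import pytest

from demohist import (
    Demography,
    SimulationRequest,
    STUDY_LAYOUT,
    build_folded_joint_sfs,
    expected_sfs,
    simulate_genotype_matrix,
    simulate_joint_sfs,
)
from demohist._reference import reference_expected_sfs
from demohist.engine import SimulationError
from demohist.genotypes import MISSING
from demohist.models import MigrationEpoch
from demohist.sfs import canonical_mask


PANMICTIC = Demography(ne_nl=10_000.0, panmictic=True)


class TestSimulateJointSFS:
    def test_zero_mutation_rate_gives_empty_sfs(self):
        req = SimulationRequest(
            demography=PANMICTIC, n1=4, n2=4, num_loci=50, seed=1, theta=0.0
        )
        s = simulate_joint_sfs(req)
        assert s.total() == 0.0

    def test_watterson_segregating_sites(self):
        # E[S per locus] = theta * sum_{i<n} 1/i for a panmictic sample
        n, theta, loci = 10, 1.0, 4000
        req = SimulationRequest(
            demography=PANMICTIC, n1=5, n2=5, num_loci=loci, seed=7,
            theta=theta, locus_length=1,
        )
        s = simulate_joint_sfs(req)
        a_n = sum(1.0 / i for i in range(1, n))
        mean_s = s.total() / loci
        # 3 standard errors using the theoretical per-locus variance
        var = theta * a_n + theta**2 * sum(1.0 / i**2 for i in range(1, n))
        assert abs(mean_s - theta * a_n) < 3 * np.sqrt(var / loci)

    def test_deep_isolation_shares_almost_no_polymorphism(self):
        dem = Demography(ne_nl=2000, ne_es=2000, ne_anc=2000, t_div=80_000)
        req = SimulationRequest(
            demography=dem, n1=6, n2=6, num_loci=4000, seed=9, theta=0.5,
            locus_length=1,
        )
        s = simulate_joint_sfs(req)
        shared = s.counts[1:, 1:].sum()
        assert shared / s.total() < 0.01

    def test_seeded_runs_identical(self):
        req = SimulationRequest(
            demography=PANMICTIC, n1=4, n2=4, num_loci=200, seed=3, theta=1.0
        )
        np.testing.assert_array_equal(
            simulate_joint_sfs(req).counts, simulate_joint_sfs(req).counts
        )


class TestExpectedSFS:
    def test_normalization(self):
        e = expected_sfs(PANMICTIC, 6, 6, 500, seed=2)
        assert e.counts[~e.mask].sum() == pytest.approx(1.0, abs=1e-12)
        assert e.p_floor == pytest.approx(1 / (10 * 500 * (~e.mask).sum()))

    def test_symmetric_island_model_symmetric_sfs(self):
        m = 1.0 / (2 * 5000)
        dem = Demography(
            ne_nl=5000, ne_es=5000, ne_anc=5000, t_div=100_000,
            migration_epochs=(MigrationEpoch(0.0, 100_000.0, m, m),),
        )
        e = expected_sfs(dem, 6, 6, 30_000, seed=4)
        asym = np.max(np.abs(e.counts - e.counts.T))
        assert asym < 0.01

    def test_matches_reference_simulator_isolation(self):
        dem = Demography(ne_nl=5000, ne_es=8000, ne_anc=10_000, t_div=15_000)
        e_fast = expected_sfs(dem, 4, 4, 20_000, seed=3)
        e_ref = reference_expected_sfs(dem, 4, 4, 8000, seed=4)
        assert np.max(np.abs(e_fast.counts - e_ref.counts)) < 0.012

    def test_matches_reference_simulator_one_way_migration(self):
        dem = Demography(
            ne_nl=5000, ne_es=5000, ne_anc=5000, t_div=200_000,
            migration_epochs=(MigrationEpoch(0.0, 200_000.0, 5e-4, 0.0),),
        )
        e_fast = expected_sfs(dem, 4, 4, 20_000, seed=5)
        e_ref = reference_expected_sfs(dem, 4, 4, 8000, seed=6)
        assert np.max(np.abs(e_fast.counts - e_ref.counts)) < 0.012

    def test_panmictic_matches_neutral_shape(self):
        # pooled folded SFS of a panmictic deme follows 1/i + 1/(2n-i)
        n = 10
        e = expected_sfs(PANMICTIC, 5, 5, 40_000, seed=8)
        pooled = np.zeros(n // 2 + 1)
        for i in range(6):
            for j in range(6):
                if not e.mask[i, j]:
                    pooled[i + j] += e.counts[i, j]
        want = np.zeros(n // 2 + 1)
        for k in range(1, n // 2 + 1):
            want[k] = 1.0 / k + (1.0 / (n - k) if k != n - k else 0.0)
        want /= want.sum()
        np.testing.assert_allclose(pooled[1:], want[1:], atol=0.01)

    def test_migration_increases_shared_polymorphism(self):
        shared = []
        for mig in (0.0, 2e-5, 2e-4):
            dem = Demography(
                ne_nl=5000, ne_es=5000, ne_anc=5000, t_div=60_000,
                migration_epochs=(
                    (MigrationEpoch(0.0, 60_000.0, mig, mig),) if mig else ()
                ),
            )
            e = expected_sfs(dem, 4, 4, 8000, seed=11)
            shared.append(e.counts[1:, 1:].sum())
        assert shared[0] < shared[1] < shared[2]


class TestGenotypeSimulation:
    LAYOUT = (("P1", 4, "NL"), ("P2", 3, "NL"), ("P3", 5, "ES"))

    def request(self, missingness=0.0, loci=300, seed=13):
        dem = Demography(ne_nl=8000, ne_es=8000, ne_anc=8000, t_div=20_000)
        return SimulationRequest(
            demography=dem, n1=14, n2=10, num_loci=loci, seed=seed,
            theta=1.0, missingness=missingness,
        )

    def test_sfs_consistency_with_direct_counting(self):
        ds = simulate_genotype_matrix(self.request(), self.LAYOUT)
        g, pm = ds.genotypes, ds.population_map
        s = build_folded_joint_sfs(g, pm, "NL", "ES", (14, 10))
        # independent counting of the same genotype matrix
        nl = [i for i, ind in enumerate(g.individual_ids)
              if pm.population_to_group[pm.individual_to_population[ind]] == "NL"]
        es = [i for i in range(g.n_individuals) if i not in nl]
        direct = np.zeros((15, 11))
        for locus in g.genotypes.T:
            i, j = locus[nl].sum(), locus[es].sum()
            if 2 * (i + j) < 24:
                direct[i, j] += 1
            elif 2 * (i + j) > 24:
                direct[14 - i, 10 - j] += 1
            else:
                direct[i, j] += 0.5
                direct[14 - i, 10 - j] += 0.5
        np.testing.assert_allclose(s.counts, direct, atol=1e-9)

    def test_missingness_rate_binomial(self):
        ds = simulate_genotype_matrix(self.request(missingness=0.2, loci=800), self.LAYOUT)
        rate = (ds.genotypes.genotypes != MISSING).mean()
        assert rate == pytest.approx(0.8, abs=0.02)

    def test_bit_identical_at_fixed_seed(self):
        d1 = simulate_genotype_matrix(self.request(missingness=0.1), self.LAYOUT)
        d2 = simulate_genotype_matrix(self.request(missingness=0.1), self.LAYOUT)
        assert d1.genotypes.equals(d2.genotypes)

    def test_study_layout_shape(self):
        dem = Demography(ne_nl=5000, ne_es=5000, ne_anc=5000, t_div=10_000)
        req = SimulationRequest(
            demography=dem, n1=144, n2=80, num_loci=40, seed=21, theta=0.5
        )
        ds = simulate_genotype_matrix(req, STUDY_LAYOUT)
        assert ds.genotypes.n_individuals == 112
        assert len(ds.population_map.populations) == 11
        sizes = sorted(
            len(v) for v in ds.population_map.population_indices(ds.genotypes).values()
        )
        assert sizes == [5, 7, 8, 9, 9, 10, 11, 12, 13, 14, 14]
        assert set(ds.population_map.groups) == {"NL", "ES"}

    def test_odd_allele_count_rejected(self):
        dem = Demography(ne_nl=5000, ne_es=5000, ne_anc=5000, t_div=10_000)
        req = SimulationRequest(
            demography=dem, n1=7, n2=10, num_loci=10, seed=1, theta=1.0
        )
        with pytest.raises(SimulationError):
            simulate_genotype_matrix(req, (("P1", 3, "NL"), ("P2", 5, "ES")))

    def test_layout_mismatch_rejected(self):
        with pytest.raises(SimulationError, match="inconsistent"):
            simulate_genotype_matrix(self.request(), (("P1", 2, "NL"), ("P3", 5, "ES")))


class TestRequestValidation:
    def test_bad_requests(self):
        with pytest.raises(SimulationError):
            SimulationRequest(demography=PANMICTIC, n1=1, n2=4, num_loci=10, seed=1, theta=1.0)
        with pytest.raises(SimulationError):
            SimulationRequest(demography=PANMICTIC, n1=4, n2=4, num_loci=0, seed=1, theta=1.0)
        with pytest.raises(SimulationError):
            SimulationRequest(demography=PANMICTIC, n1=4, n2=4, num_loci=10, seed=1)
        with pytest.raises(SimulationError):
            SimulationRequest(
                demography=PANMICTIC, n1=4, n2=4, num_loci=10, seed=1, theta=-1.0
            )
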