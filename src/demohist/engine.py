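"""Coalescent simulation engine: synthetic data and expected spectra.

Loci are unlinked and exchangeable (no within-locus recombination), the
treatment under which GBS SNPs enter the SFS composite likelihood as
independent observations.  Genealogy generation is delegated to msprime
behind this module's operation contracts; an independent minimal
structured-coalescent implementation lives in :mod:`demohist._reference`
and is used as a cross-check oracle in the test suite.

All stochastic operations take an explicit seed; there is no global RNG
state anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import msprime
import numpy as np

from .genotypes import MISSING, GenotypeMatrix, PopulationMap
from .models import Demography
from .sfs import FoldedJointSFS, canonical_mask, fold_unfolded

__all__ = [
    "SimulationRequest",
    "SimulatedDataset",
    "STUDY_LAYOUT",
    "to_msprime",
    "simulate_joint_sfs",
    "simulate_genotype_matrix",
    "expected_sfs",
]


class SimulationError(ValueError):
    pass


#: Sampling layout emulating the study system: 11 populations in 2 groups
#: (7 montane NL populations, 4 eastern ES populations), 5-14 diploid
#: individuals per population, 112 individuals in total.
STUDY_LAYOUT: tuple[tuple[str, int, str], ...] = (
    ("YDS", 8, "ES"),
    ("WYS", 9, "ES"),
    ("LXS1", 9, "ES"),
    ("LXS2", 14, "ES"),
    ("NLE1", 12, "NL"),
    ("NLE2", 10, "NL"),
    ("NLW1", 11, "NL"),
    ("NLW2", 5, "NL"),
    ("NLW3", 13, "NL"),
    ("NLW4", 14, "NL"),
    ("NLW5", 7, "NL"),
)


@dataclass(frozen=True)
class SimulationRequest:
    """One simulation job: a demography, sample sizes, loci, mutation, seed.

    ``n1`` and ``n2`` are allele copies (haploid sample sizes) drawn from
    demes NL and ES (from the single deme for a panmictic demography).
    Mutation is specified either as ``theta`` per locus (``4*Ne_NL*u*L``)
    or as ``mutation_rate`` per site per generation with ``locus_length``
    sites per locus.
    """

    demography: Demography
    n1: int
    n2: int
    num_loci: int
    seed: int
    locus_length: int = 100
    mutation_rate: Optional[float] = None
    theta: Optional[float] = None
    missingness: float = 0.0

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise SimulationError("sample sizes must be >= 2 allele copies")
        if self.num_loci < 1:
            raise SimulationError("need at least one locus")
        if self.theta is None and self.mutation_rate is None:
            raise SimulationError("specify theta or mutation_rate")
        if (self.theta is not None and self.theta < 0) or (
            self.mutation_rate is not None and self.mutation_rate < 0
        ):
            raise SimulationError("mutation parameter must be >= 0")
        if not 0.0 <= self.missingness < 1.0:
            raise SimulationError("missingness must be in [0, 1)")

    @property
    def per_site_rate(self) -> float:
        if self.mutation_rate is not None:
            return self.mutation_rate
        # theta per locus = 4 * Ne_NL * u * locus_length
        return self.theta / (4.0 * self.demography.ne_nl * self.locus_length)


@dataclass
class SimulatedDataset:
    """A simulated genotype matrix plus the provenance to regenerate it."""

    genotypes: GenotypeMatrix
    population_map: PopulationMap
    demography: Demography
    seed: int
    layout: tuple[tuple[str, int, str], ...]
    total_sites: float
    mutation_rate: float


# ---------------------------------------------------------------------------
# demography conversion
# ---------------------------------------------------------------------------

def to_msprime(dem: Demography) -> msprime.Demography:
    """Translate the event-based description into an msprime demography.

    Migration uses the backward (lineage-movement) convention: forward
    migration NL -> ES at proportion ``m`` means lineages sampled in ES
    move to NL at rate ``m`` as time runs backward.
    """
    dem.validate()
    d = msprime.Demography()
    if dem.panmictic:
        d.add_population(name="POP", initial_size=dem.ne_nl)
        return d
    growth_nl = 0.0
    growth_es = 0.0
    if dem.expansion_deme == "NL":
        growth_nl = np.log(dem.ne_nl / dem.pre_expansion_size) / dem.expansion_onset
    elif dem.expansion_deme == "ES":
        growth_es = np.log(dem.ne_es / dem.pre_expansion_size) / dem.expansion_onset
    d.add_population(name="NL", initial_size=dem.ne_nl, growth_rate=growth_nl)
    d.add_population(name="ES", initial_size=dem.ne_es, growth_rate=growth_es)
    d.add_population(name="ANC", initial_size=dem.ne_anc)

    if dem.expansion_deme is not None:
        d.add_population_parameters_change(
            time=dem.expansion_onset,
            population=dem.expansion_deme,
            initial_size=dem.pre_expansion_size,
            growth_rate=0.0,
        )
    if dem.bottleneck is not None:
        b = dem.bottleneck
        pre_size = dem.ne_nl if b.deme == "NL" else dem.ne_es
        d.add_population_parameters_change(
            time=b.start, population=b.deme, initial_size=b.size
        )
        d.add_population_parameters_change(
            time=b.start + b.duration, population=b.deme, initial_size=pre_size
        )
    for ep in dem.migration_epochs:
        # lineages in ES move to NL (forward NL -> ES) and vice versa
        if ep.start == 0.0:
            d.set_migration_rate(source="ES", dest="NL", rate=ep.m_nl_to_es)
            d.set_migration_rate(source="NL", dest="ES", rate=ep.m_es_to_nl)
        else:
            d.add_migration_rate_change(
                time=ep.start, source="ES", dest="NL", rate=ep.m_nl_to_es
            )
            d.add_migration_rate_change(
                time=ep.start, source="NL", dest="ES", rate=ep.m_es_to_nl
            )
        if ep.end < dem.t_div:
            d.add_migration_rate_change(time=ep.end, source="ES", dest="NL", rate=0.0)
            d.add_migration_rate_change(time=ep.end, source="NL", dest="ES", rate=0.0)
    d.add_population_split(time=dem.t_div, derived=["NL", "ES"], ancestral="ANC")
    d.sort_events()
    return d


_FOLD_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _fold_operator(n1: int, n2: int) -> np.ndarray:
    """Matrix applying :func:`fold_unfolded` to a raveled spectrum."""
    key = (n1, n2)
    if key not in _FOLD_CACHE:
        dim = (n1 + 1) * (n2 + 1)
        eye = np.eye(dim)
        cols = [
            fold_unfolded(eye[:, c].reshape(n1 + 1, n2 + 1)).ravel()
            for c in range(dim)
        ]
        _FOLD_CACHE[key] = np.column_stack(cols)
    return _FOLD_CACHE[key]


def _msprime_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint64) % (2**31 - 2) + 1


def _sample_config(dem: Demography, n1: int, n2: int, ploidy: int):
    """Sample sets in allele copies; the population model stays on the
    diploid time scale (coalescence rate 1/(2N)) regardless of sample
    ploidy."""
    if dem.panmictic:
        if (n1 + n2) % ploidy:
            raise SimulationError("sample size not divisible by ploidy")
        return [msprime.SampleSet((n1 + n2) // ploidy, population="POP", ploidy=ploidy)]
    if n1 % ploidy or n2 % ploidy:
        raise SimulationError("sample sizes not divisible by ploidy")
    return [
        msprime.SampleSet(n1 // ploidy, population="NL", ploidy=ploidy),
        msprime.SampleSet(n2 // ploidy, population="ES", ploidy=ploidy),
    ]


def _sample_sets(ts, dem: Demography, n1: int, n2: int):
    if dem.panmictic:
        samples = ts.samples()
        return samples[:n1], samples[n1:]
    return ts.samples(population=0), ts.samples(population=1)


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------

def simulate_joint_sfs(req: SimulationRequest) -> FoldedJointSFS:
    """Simulate unlinked loci under the structured coalescent and return
    the folded joint SFS of the mutations (infinite-sites model)."""
    msp_dem = to_msprime(req.demography)
    anc_seed, mut_master = _msprime_seeds(req.seed, 2)
    mut_seeds = np.random.SeedSequence(int(mut_master)).generate_state(
        req.num_loci, dtype=np.uint64
    ) % (2**31 - 2) + 1
    reps = msprime.sim_ancestry(
        samples=_sample_config(req.demography, req.n1, req.n2, ploidy=1),
        ploidy=2,
        demography=msp_dem,
        sequence_length=req.locus_length,
        num_replicates=req.num_loci,
        random_seed=int(anc_seed),
    )
    unfolded = np.zeros((req.n1 + 1, req.n2 + 1))
    rate = req.per_site_rate
    for li, ts in enumerate(reps):
        if rate == 0.0:
            continue
        mts = msprime.sim_mutations(
            ts, rate=rate, random_seed=int(mut_seeds[li]), discrete_genome=False
        )
        if mts.num_sites == 0:
            continue
        s1, s2 = _sample_sets(mts, req.demography, req.n1, req.n2)
        unfolded += mts.allele_frequency_spectrum(
            sample_sets=[s1, s2], mode="site", polarised=True, span_normalise=False
        )
    return FoldedJointSFS(
        counts=fold_unfolded(unfolded),
        n1=req.n1,
        n2=req.n2,
        total_sites=float(req.num_loci * req.locus_length),
        mutation_rate=rate,
    )


def expected_sfs(
    demography: Demography, n1: int, n2: int, n_sims: int, seed: int
) -> FoldedJointSFS:
    """Monte-Carlo expected folded joint SFS under a demography.

    Averages the branch-mode frequency spectrum over ``n_sims`` independent
    genealogies: the returned (unmasked) entries are probabilities of each
    minor-allele configuration conditional on a site being polymorphic, and
    sum to 1.  ``branch_total`` carries the mean branch length per site
    subtending polymorphic classes (used to anchor absolute scale when a
    mutation rate is known), and ``p_floor`` the recommended probability
    floor for likelihood evaluation at this Monte-Carlo resolution.
    """
    if n_sims < 1:
        raise SimulationError("n_sims must be >= 1")
    msp_dem = to_msprime(demography)
    (anc_seed,) = _msprime_seeds(seed, 1)
    reps = msprime.sim_ancestry(
        samples=_sample_config(demography, n1, n2, ploidy=1),
        ploidy=2,
        demography=msp_dem,
        sequence_length=1,
        num_replicates=n_sims,
        random_seed=int(anc_seed),
    )
    mask = canonical_mask(n1, n2)
    unmasked = ~mask
    raw = np.empty((n_sims, (n1 + 1) * (n2 + 1)))
    s1 = s2 = None
    for i, ts in enumerate(reps):
        if s1 is None:
            s1, s2 = _sample_sets(ts, demography, n1, n2)
        raw[i] = ts.allele_frequency_spectrum(
            sample_sets=[s1, s2], mode="branch", polarised=True,
            span_normalise=False,
        ).ravel()
    # folding is linear: apply it to all genealogies at once
    fold_map = _fold_operator(n1, n2)
    per_tree = raw @ fold_map.T
    fsum = per_tree.sum(axis=0).reshape(n1 + 1, n2 + 1)
    fsumsq = (per_tree**2).sum(axis=0).reshape(n1 + 1, n2 + 1)
    totals = per_tree[:, unmasked.ravel()].sum(axis=1)
    tot_sum = float(totals.sum())
    tot_sumsq = float((totals**2).sum())
    folded = fsum / n_sims
    branch_total = float(folded[unmasked].sum())
    if branch_total <= 0:
        raise SimulationError("degenerate expectation: no polymorphic branch mass simulated")
    probs = np.where(mask, 0.0, folded / branch_total)
    n_entries = int(unmasked.sum())
    # relative Monte-Carlo variance of each cell mean and of the total,
    # used downstream to debias the composite log-likelihood (the
    # first-order E[ln p-hat] = ln p - Var/2p^2 noise penalty otherwise
    # favours demographies with low genealogy-to-genealogy variance)
    if n_sims > 1:
        var_cell = (fsumsq / n_sims - folded**2) / max(n_sims - 1, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_var = np.where(folded > 0, var_cell / np.maximum(folded, 1e-300) ** 2, 0.0)
        rel_var[mask] = 0.0
        mean_tot = tot_sum / n_sims
        var_tot = (tot_sumsq / n_sims - mean_tot**2) / max(n_sims - 1, 1)
        rel_var_total = float(var_tot / mean_tot**2)
    else:
        rel_var = None
        rel_var_total = None
    return FoldedJointSFS(
        counts=probs,
        n1=n1,
        n2=n2,
        mask=mask,
        branch_total=branch_total,
        p_floor=1.0 / (10.0 * n_sims * n_entries),
        mc_rel_var=rel_var,
        mc_rel_var_total=rel_var_total,
    )


def simulate_genotype_matrix(
    req: SimulationRequest,
    layout: Sequence[tuple[str, int, str]] = STUDY_LAYOUT,
) -> SimulatedDataset:
    """Simulate a diploid genotype matrix with a population/group layout.

    ``layout`` rows are ``(population, n_individuals, group)`` with groups
    in {NL, ES} (any single group name for a panmictic demography).
    Diploid genotypes are formed by pairing simulated haplotypes; optional
    uniform missingness is applied afterwards.  Bit-identical across runs
    at a fixed seed.
    """
    groups: dict[str, list[tuple[str, int]]] = {}
    for pop, n_ind, grp in layout:
        groups.setdefault(grp, []).append((pop, n_ind))
    if req.demography.panmictic:
        if len(groups) < 1:
            raise SimulationError("layout must name at least one group")
    elif set(groups) != {"NL", "ES"}:
        raise SimulationError(f"layout groups {sorted(groups)} must be NL and ES")
    n_by_group = {grp: sum(n for _, n in pops) for grp, pops in groups.items()}
    if req.n1 % 2 or req.n2 % 2:
        raise SimulationError("odd allele counts cannot be paired into diploids")
    expect = (
        {"NL": req.n1 // 2, "ES": req.n2 // 2}
        if not req.demography.panmictic
        else {next(iter(groups)): (req.n1 + req.n2) // 2}
    )
    if n_by_group != expect:
        raise SimulationError(
            f"layout individuals per group {n_by_group} inconsistent with "
            f"sample sizes {expect}"
        )

    msp_dem = to_msprime(req.demography)
    anc_seed, mut_master, miss_seed = _msprime_seeds(req.seed, 3)
    mut_seeds = np.random.SeedSequence(int(mut_master)).generate_state(
        req.num_loci, dtype=np.uint64
    ) % (2**31 - 2) + 1
    reps = msprime.sim_ancestry(
        samples=_sample_config(req.demography, req.n1, req.n2, ploidy=2),
        ploidy=2,
        demography=msp_dem,
        sequence_length=req.locus_length,
        num_replicates=req.num_loci,
        random_seed=int(anc_seed),
    )
    rate = req.per_site_rate
    blocks: list[np.ndarray] = []
    locus_ids: list[str] = []
    for li, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=rate, random_seed=int(mut_seeds[li]), discrete_genome=False
        )
        if mts.num_sites == 0:
            continue
        H = mts.genotype_matrix()  # sites x haploid genomes
        dosage = (H[:, ::2] + H[:, 1::2]).astype(np.int8)  # sites x individuals
        blocks.append(dosage.T)
        locus_ids.extend(f"L{li}_{s}" for s in range(mts.num_sites))

    n_ind_total = sum(n for _, n, _ in layout)
    geno = (
        np.concatenate(blocks, axis=1)
        if blocks
        else np.zeros((n_ind_total, 0), dtype=np.int8)
    )
    if req.missingness > 0 and geno.size:
        rng = np.random.default_rng(int(miss_seed))
        geno = np.where(rng.random(geno.shape) < req.missingness, MISSING, geno)

    # msprime orders sampled individuals NL first, then ES (layout order inside)
    individual_ids: list[str] = []
    ind_to_pop: dict[str, str] = {}
    pop_to_group: dict[str, str] = {}
    group_order = ["NL", "ES"] if not req.demography.panmictic else list(groups)
    for grp in group_order:
        for pop, n_ind in groups.get(grp, []):
            pop_to_group[pop] = grp
            for i in range(n_ind):
                ind = f"{pop}_{i + 1}"
                individual_ids.append(ind)
                ind_to_pop[ind] = pop
    gm = GenotypeMatrix(individual_ids, locus_ids, geno)
    pm = PopulationMap(ind_to_pop, pop_to_group)
    return SimulatedDataset(
        genotypes=gm,
        population_map=pm,
        demography=req.demography,
        seed=req.seed,
        layout=tuple(layout),
        total_sites=float(req.num_loci * req.locus_length),
        mutation_rate=rate,
    )
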