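"""Shared fixtures: small genotype matrices built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from demohist import GenotypeMatrix, PopulationMap
from demohist.genotypes import MISSING


def make_matrix(genotypes, individual_ids=None, locus_ids=None) -> GenotypeMatrix:
    g = np.asarray(genotypes, dtype=np.int8)
    n, l = g.shape
    return GenotypeMatrix(
        individual_ids=individual_ids or [f"ind{i}" for i in range(n)],
        locus_ids=locus_ids or [f"L{j}" for j in range(l)],
        genotypes=g,
    )


@pytest.fixture
def eleven_pop_map() -> PopulationMap:
    """11 populations x 2 individuals, two groups (7 NL + 4 ES pops)."""
    ind_to_pop = {}
    pop_to_group = {}
    pops = [f"NLP{i}" for i in range(1, 8)] + [f"ESP{i}" for i in range(1, 5)]
    for p in pops:
        pop_to_group[p] = "NL" if p.startswith("NLP") else "ES"
        for k in range(2):
            ind_to_pop[f"{p}_i{k}"] = p
    return PopulationMap(ind_to_pop, pop_to_group)


@pytest.fixture
def twelve_locus_matrix(eleven_pop_map) -> GenotypeMatrix:
    """22 individuals x 12 loci with planted filter violations.

    Columns 0-2: minor allele frequency below 0.05 (one heterozygote).
    Columns 3-4: genotyped everywhere but with one individual missing in
        eight of the eleven populations, so only three populations reach the
        80% within-population genotyping rate.
    Column 5: every genotyped individual heterozygous (Ho = 1 > 0.5).
    Columns 6-7: data confined to four populations (below the five-
        population minimum), perfectly genotyped there.
    Columns 8-11: clean (MAF >= 0.05, complete, moderate heterozygosity).
    """
    inds = list(eleven_pop_map.individual_to_population)
    n = len(inds)  # 22
    g = np.zeros((n, 12), dtype=np.int8)
    # (a) three low-MAF loci: a single heterozygote -> p = 1/44 < 0.05
    for j in (0, 1, 2):
        g[j, j] = 1
    # (b) two low-rate loci: alt present, one of two individuals missing in
    # populations 1..8 (rate 0.5 < 0.8 there; only 3 pops meet the rate)
    for j in (3, 4):
        g[:, j] = [1 if i % 2 == 0 else 0 for i in range(n)]
        for p_idx in range(8):
            g[2 * p_idx, j] = MISSING
    # (c) one excess-heterozygosity locus
    g[:, 5] = 1
    # (d) two few-population loci: only the first 4 populations carry data
    for j in (6, 7):
        g[:, j] = MISSING
        g[: 8, j] = [0, 1, 1, 2, 0, 1, 2, 1]
    # clean loci
    for j in (8, 9, 10, 11):
        g[:, j] = [(i + j) % 3 for i in range(n)]
    return make_matrix(g, individual_ids=inds)


@pytest.fixture
def amova_toy():
    """12 individuals, 2 groups x 2 populations x 3 individuals, 5 loci.

    Strong among-group differentiation with a little within-group and
    within-population variation; no missingness, so closed-form balanced
    AMOVA algebra applies.
    """
    genotypes = [
        # group A, population P1
        [0, 0, 0, 1, 0],
        [0, 0, 1, 1, 0],
        [0, 1, 0, 1, 0],
        # group A, population P2
        [0, 0, 0, 2, 1],
        [1, 0, 0, 2, 1],
        [0, 0, 1, 2, 1],
        # group B, population P3
        [2, 2, 2, 0, 2],
        [2, 2, 1, 0, 2],
        [2, 1, 2, 0, 2],
        # group B, population P4
        [2, 2, 2, 1, 1],
        [1, 2, 2, 1, 1],
        [2, 2, 2, 1, 2],
    ]
    inds = [f"i{k}" for k in range(12)]
    g = make_matrix(genotypes, individual_ids=inds)
    pops = ["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3 + ["P4"] * 3
    pm = PopulationMap(
        dict(zip(inds, pops)), {"P1": "A", "P2": "A", "P3": "B", "P4": "B"}
    )
    return g, pm
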