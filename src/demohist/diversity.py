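"""Per-population diversity, pairwise Fst, and hierarchical AMOVA.

Expected heterozygosity uses Nei's unbiased small-sample correction
``2n/(2n-1) * (1 - p^2 - q^2)`` — material at the 5-14 individuals per
population typical of the sampled system.  Pairwise differentiation is the
Weir & Cockerham theta (multilocus ratio of variance-component sums;
slightly negative values are reported as-is, not clamped).  The AMOVA is
the three-level nested decomposition (among groups / among populations
within groups / within populations) on individual squared Euclidean
distances between alternate-allele dosage vectors, with permutation
significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "observed_heterozygosity",
    "expected_heterozygosity",
    "nucleotide_diversity",
    "diversity_table",
    "pairwise_fst",
    "fst_matrix",
    "amova",
    "fixation_indices",
    "AmovaResult",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """A statistic has no defined value for the given data."""


def _pop_rows(g: GenotypeMatrix, pop) -> np.ndarray:
    """Rows of ``g`` for a population given as labels or indices."""
    pop = list(pop)
    if pop and isinstance(pop[0], str):
        lookup = {ind: i for i, ind in enumerate(g.individual_ids)}
        return np.asarray([lookup[p] for p in pop], dtype=int)
    return np.asarray(pop, dtype=int)


def observed_heterozygosity(g: GenotypeMatrix, pop: Sequence) -> float:
    """Mean over loci of the heterozygote fraction among non-missing calls."""
    X = g.genotypes[_pop_rows(g, pop)]
    nonmiss = (X != MISSING).sum(axis=0)
    ok = nonmiss > 0
    if not ok.any():
        raise UndefinedStatisticError("population has no non-missing genotypes")
    het = (X == 1).sum(axis=0)
    return float(np.mean(het[ok] / nonmiss[ok]))


def expected_heterozygosity(g: GenotypeMatrix, pop: Sequence) -> float:
    """Mean over loci of Nei's unbiased gene diversity 2n/(2n-1)(1-p^2-q^2)."""
    X = g.genotypes[_pop_rows(g, pop)]
    nonmiss = (X != MISSING).sum(axis=0)
    ok = nonmiss > 0
    if not ok.any():
        raise UndefinedStatisticError("population has no non-missing genotypes")
    alt = np.where(X != MISSING, X, 0).sum(axis=0)
    n = nonmiss[ok].astype(float)
    p = alt[ok] / (2.0 * n)
    h = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
    return float(np.mean(h))


def nucleotide_diversity(g: GenotypeMatrix, pop: Sequence) -> float:
    """Mean over loci of per-site pairwise diversity 2j(k-j) / (k(k-1))."""
    X = g.genotypes[_pop_rows(g, pop)]
    k = 2.0 * (X != MISSING).sum(axis=0)
    ok = k >= 2
    if not ok.any():
        raise UndefinedStatisticError("population has no locus with >= 2 alleles")
    j = np.where(X != MISSING, X, 0).sum(axis=0)[ok].astype(float)
    k = k[ok]
    return float(np.mean(2.0 * j * (k - j) / (k * (k - 1.0))))


def diversity_table(g: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    """Per-population n / He / Ho / Pi table (populations in map order)."""
    rows = []
    for pop, idx in pm.population_indices(g).items():
        rows.append(
            {
                "population": pop,
                "group": pm.population_to_group[pop],
                "n": len(idx),
                "He": expected_heterozygosity(g, idx),
                "Ho": observed_heterozygosity(g, idx),
                "Pi": nucleotide_diversity(g, idx),
            }
        )
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(X1: np.ndarray, X2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus W&C variance components (a, b, c) for two samples.

    Loci where either sample has < 2 non-missing diploids are dropped.
    """
    r = 2.0
    n1 = (X1 != MISSING).sum(axis=0).astype(float)
    n2 = (X2 != MISSING).sum(axis=0).astype(float)
    ok = (n1 >= 2) & (n2 >= 2)
    n1, n2 = n1[ok], n2[ok]
    X1, X2 = X1[:, ok], X2[:, ok]
    p1 = np.where(X1 != MISSING, X1, 0).sum(axis=0) / (2 * n1)
    p2 = np.where(X2 != MISSING, X2, 0).sum(axis=0) / (2 * n2)
    h1 = (X1 == 1).sum(axis=0) / n1
    h2 = (X2 == 1).sum(axis=0) / n2

    nbar = (n1 + n2) / r
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(g: GenotypeMatrix, pop_a: Sequence, pop_b: Sequence) -> float:
    """Weir & Cockerham theta between two populations (ratio of sums)."""
    a, b, c = _wc_components(
        g.genotypes[_pop_rows(g, pop_a)], g.genotypes[_pop_rows(g, pop_b)]
    )
    denom = (a + b + c).sum()
    if a.size == 0 or denom == 0:
        raise UndefinedStatisticError(
            "theta undefined: no shared informative locus between the populations"
        )
    return float(a.sum() / denom)


def fst_matrix(g: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    pops = pm.populations
    idx = pm.population_indices(g)
    out = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for i, p in enumerate(pops):
        out.loc[p, p] = 0.0
        for q in pops[i + 1 :]:
            theta = pairwise_fst(g, idx[p], idx[q])
            out.loc[p, q] = out.loc[q, p] = theta
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Three-level AMOVA table with fixation indices and permutation p-values."""

    df: dict[str, int]
    ss: dict[str, float]
    sigma2: dict[str, float]
    percent: dict[str, float]
    fct: float
    fsc: float
    fst: float
    p_values: dict[str, Optional[float]]
    n_permutations: int
    seed: Optional[int]

    LEVELS = ("among_groups", "among_populations_within_groups", "within_populations")

    def table(self) -> pd.DataFrame:
        rows = []
        for lv in self.LEVELS:
            rows.append(
                {
                    "source": lv.replace("_", " "),
                    "df": self.df[lv],
                    "sum_of_squares": self.ss[lv],
                    "variance_component": self.sigma2[lv],
                    "percent_of_variation": self.percent[lv],
                }
            )
        rows.append(
            {
                "source": "total",
                "df": sum(self.df.values()),
                "sum_of_squares": sum(self.ss.values()),
                "variance_component": sum(self.sigma2.values()),
                "percent_of_variation": 100.0,
            }
        )
        return pd.DataFrame(rows).set_index("source")

    def summary(self) -> str:
        lines = [self.table().to_string(float_format=lambda v: f"{v:.5f}")]
        lines.append(
            f"Fct = {self.fct:.4f} (p = {self.p_values.get('fct')})   "
            f"Fsc = {self.fsc:.4f} (p = {self.p_values.get('fsc')})   "
            f"Fst = {self.fst:.4f} (p = {self.p_values.get('fst')})"
        )
        if any(v < 0 for v in self.sigma2.values()):
            lines.append("note: negative variance component(s) reported unclamped")
        return "\n".join(lines)


def fixation_indices(
    sigma_a: float, sigma_b: float, sigma_c: float
) -> tuple[float, float, float]:
    """(Fct, Fsc, Fst) from the three AMOVA variance components.

    Fct = sa/sT, Fsc = sb/(sb+sc), Fst = (sa+sb)/sT; the identity
    Fst = Fct + (1-Fct) Fsc holds algebraically and is asserted.
    """
    total = sigma_a + sigma_b + sigma_c
    if not np.isfinite(total) or total <= 0:
        raise UndefinedStatisticError("total variance must be positive and finite")
    if sigma_b + sigma_c == 0:
        raise UndefinedStatisticError("Fsc undefined: sigma_b + sigma_c = 0")
    fct = sigma_a / total
    fsc = sigma_b / (sigma_b + sigma_c)
    fst = (sigma_a + sigma_b) / total
    assert abs(fst - (fct + (1 - fct) * fsc)) < 1e-9
    return float(fct), float(fsc), float(fst)


def _squared_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances on dosage vectors with
    pairwise deletion of missing loci, rescaled to the full locus count."""
    L = X.shape[1]
    M = (X != MISSING).astype(float)
    A = np.where(X != MISSING, X, 0).astype(float)
    A2 = A**2
    shared = M @ M.T
    cross = A @ A.T
    sq_i = A2 @ M.T
    d2 = sq_i + sq_i.T - 2 * cross
    if (shared[~np.eye(len(X), dtype=bool)] == 0).any():
        raise UndefinedStatisticError(
            "a pair of individuals shares no genotyped locus"
        )
    d2 = d2 / np.maximum(shared, 1) * L
    np.fill_diagonal(d2, 0.0)
    return d2


def _amova_ss(d2: np.ndarray, pops: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """(SS among groups, SS among pops within groups, SS within pops)."""
    n = len(pops)
    tri = np.triu_indices(n, k=1)

    def _ss_within(labels: np.ndarray) -> float:
        ss = 0.0
        for lab in np.unique(labels):
            sel = labels == lab
            ss += d2[np.ix_(sel, sel)][np.triu_indices(sel.sum(), k=1)].sum() / sel.sum()
        return ss

    ss_total = d2[tri].sum() / n
    ss_wp = _ss_within(pops)
    ss_wg = _ss_within(groups)
    return ss_total - ss_wg, ss_wg - ss_wp, ss_wp


def _amova_components(
    d2: np.ndarray, pops: np.ndarray, groups: np.ndarray
) -> tuple[tuple[float, float, float], tuple[int, int, int], tuple[float, float, float]]:
    """Sums of squares, df, and variance components by the nested
    expected-mean-squares (moments) equations with unbalanced-design
    coefficients."""
    n = len(pops)
    pop_labels, pop_sizes = np.unique(pops, return_counts=True)
    grp_of_pop = {}
    for pl in pop_labels:
        gs = np.unique(groups[pops == pl])
        if len(gs) != 1:
            raise ValueError(f"population {pl} assigned to several groups")
        grp_of_pop[pl] = gs[0]
    grp_labels, grp_sizes_ind = np.unique(groups, return_counts=True)
    P, G = len(pop_labels), len(grp_labels)
    if G < 2:
        raise ValueError("AMOVA needs at least two groups")
    df = (G - 1, P - G, n - P)
    if df[2] == 0:
        raise UndefinedStatisticError("no within-population degrees of freedom")

    ss_ag, ss_ap, ss_wp = _amova_ss(d2, pops, groups)
    grp_ind = {gl: grp_sizes_ind[i] for i, gl in enumerate(grp_labels)}
    sizes = dict(zip(pop_labels, pop_sizes))
    sum_np2_over_ng = sum(
        sizes[pl] ** 2 / grp_ind[grp_of_pop[pl]] for pl in pop_labels
    )
    sum_np2_over_n = sum(sizes[pl] ** 2 for pl in pop_labels) / n
    sum_ng2_over_n = sum(v**2 for v in grp_ind.values()) / n

    n_prime = (n - sum_np2_over_ng) / df[1] if df[1] > 0 else 0.0
    n_dprime = (sum_np2_over_ng - sum_np2_over_n) / df[0]
    n_tprime = (n - sum_ng2_over_n) / df[0]

    sigma_c = ss_wp / df[2]
    sigma_b = (ss_ap / df[1] - sigma_c) / n_prime if df[1] > 0 else 0.0
    sigma_a = (ss_ag / df[0] - sigma_c - n_dprime * sigma_b) / n_tprime
    return (ss_ag, ss_ap, ss_wp), df, (sigma_a, sigma_b, sigma_c)


def amova(
    g: GenotypeMatrix,
    pm: PopulationMap,
    groups: Optional[dict[str, str]] = None,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> AmovaResult:
    """Three-level AMOVA on squared dosage distances with permutation tests.

    ``groups`` optionally overrides the population->group partition in the
    map.  Permutation schemes: individuals among populations (Fst),
    individuals among populations within groups (Fsc), and whole
    populations among groups (Fct); p-values are in
    ``[1/(n_perm+1), 1]`` and reproducible at a fixed seed.
    """
    pop_of = {p: pm.population_to_group[p] for p in pm.populations}
    if groups is not None:
        pop_of.update(groups)
    pops = np.asarray([pm.individual_to_population[i] for i in g.individual_ids])
    grp = np.asarray([pop_of[p] for p in pops])

    d2 = _squared_distance_matrix(g.genotypes)
    if d2.sum() == 0:
        raise UndefinedStatisticError(
            "zero total sum of squares: fixation indices undefined"
        )
    ss, df, sig = _amova_components(d2, pops, grp)
    fct, fsc, fst = fixation_indices(*sig)
    total = sum(sig)
    levels = AmovaResult.LEVELS
    result = AmovaResult(
        df=dict(zip(levels, df)),
        ss=dict(zip(levels, ss)),
        sigma2=dict(zip(levels, sig)),
        percent={lv: 100.0 * s / total for lv, s in zip(levels, sig)},
        fct=fct,
        fsc=fsc,
        fst=fst,
        p_values={"fct": None, "fsc": None, "fst": None},
        n_permutations=n_perm,
        seed=seed,
    )
    if n_perm > 0:
        result.p_values = _permutation_p_values(d2, pops, grp, fct, fsc, fst, n_perm, seed)
    return result


def _permutation_p_values(d2, pops, grp, fct, fsc, fst, n_perm, seed):
    rng = np.random.default_rng(seed)
    n = len(pops)
    pop_labels = np.unique(pops)
    grp_of_pop = {pl: grp[pops == pl][0] for pl in pop_labels}
    ge_fst = ge_fsc = ge_fct = 0

    def _indices(p, g_):
        try:
            return fixation_indices(*_amova_components(d2, p, g_)[2])
        except UndefinedStatisticError:
            return np.nan, np.nan, np.nan

    for _ in range(n_perm):
        # Fst: individuals permuted among all populations; group labels
        # follow each individual's (permuted) population
        pp = pops[rng.permutation(n)]
        _, _, fst_p = _indices(pp, np.asarray([grp_of_pop[x] for x in pp]))
        if fst_p >= fst - 1e-12:
            ge_fst += 1
        # Fsc: individuals permuted among populations within their group
        pp = pops.copy()
        for gl in np.unique(grp):
            sel = np.flatnonzero(grp == gl)
            pp[sel] = pp[sel[rng.permutation(len(sel))]]
        _, fsc_p, _ = _indices(pp, grp)
        if fsc_p >= fsc - 1e-12:
            ge_fsc += 1
        # Fct: whole populations permuted among groups
        perm_groups = rng.permutation([grp_of_pop[pl] for pl in pop_labels])
        mapping = dict(zip(pop_labels, perm_groups))
        fct_p, _, _ = _indices(pops, np.asarray([mapping[x] for x in pops]))
        if fct_p >= fct - 1e-12:
            ge_fct += 1
    return {
        "fst": (ge_fst + 1) / (n_perm + 1),
        "fsc": (ge_fsc + 1) / (n_perm + 1),
        "fct": (ge_fct + 1) / (n_perm + 1),
    }
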