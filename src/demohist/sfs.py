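"""Folded two-population joint site frequency spectra.

The folded joint SFS is the sufficient statistic for the demographic
inference: a matrix of site counts indexed by the minor-allele count in
each of two demes.  Folding is on the whole-(two-deme)-sample minor allele
(the easySFS / fastsimcoal convention), with a site whose overall
frequency is exactly 1/2 contributing half a count to each conjugate
entry.  Missing genotypes are handled by hypergeometric projection of each
locus down to fixed sample sizes rather than by dropping loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "FoldedJointSFS",
    "build_folded_joint_sfs",
    "project_sfs",
    "sfs_total",
    "write_sfs",
    "read_sfs",
    "fold_unfolded",
    "canonical_mask",
]


class SFSError(ValueError):
    pass


def canonical_mask(n1: int, n2: int) -> np.ndarray:
    """Excluded entries: the structural-zero region beyond the fold, the
    monomorphic corner (0, 0), and its fully-folded complement (n1, n2)."""
    i = np.arange(n1 + 1)[:, None]
    j = np.arange(n2 + 1)[None, :]
    mask = 2 * (i + j) > (n1 + n2)
    mask[0, 0] = True
    mask[n1, n2] = True
    return mask


def fold_unfolded(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded joint spectrum on the whole-sample minor allele.

    Entries beyond the fold line move to their conjugate ``(n1-i, n2-j)``;
    entries exactly on the line (overall frequency 1/2) are split equally
    between the conjugate pair.  Total mass is conserved.
    """
    u = np.asarray(unfolded, dtype=float)
    n1, n2 = u.shape[0] - 1, u.shape[1] - 1
    conj = u[::-1, ::-1]
    i = np.arange(n1 + 1)[:, None]
    j = np.arange(n2 + 1)[None, :]
    t2 = 2 * (i + j)
    s = n1 + n2
    folded = np.where(t2 < s, u + conj, np.where(t2 == s, (u + conj) / 2.0, 0.0))
    return folded


@dataclass
class FoldedJointSFS:
    """Counts of sites by minor-allele count in deme 1 x deme 2.

    ``counts[i, j]`` is the (possibly fractional, after projection) number
    of sites with ``i`` copies in deme 1 (sample size ``n1`` allele copies)
    and ``j`` in deme 2.  ``mask`` marks entries excluded from totals and
    likelihood sums.  ``total_sites`` and ``mutation_rate`` are optional
    provenance used to anchor absolute population sizes during fitting;
    ``branch_total`` is set on expected (simulated) spectra and holds the
    mean branch length per site subtending polymorphic classes.
    """

    counts: np.ndarray
    n1: int
    n2: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    total_sites: Optional[float] = None
    mutation_rate: Optional[float] = None
    branch_total: Optional[float] = None
    p_floor: Optional[float] = None
    mc_rel_var: Optional[np.ndarray] = None
    mc_rel_var_total: Optional[float] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise SFSError(
                f"counts shape {self.counts.shape} does not match sample sizes "
                f"({self.n1}, {self.n2})"
            )
        if self.mask is None:
            self.mask = canonical_mask(self.n1, self.n2)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.counts.shape:
            raise SFSError("mask shape must match counts shape")
        if (self.counts[~self.mask] < -1e-9).any():
            raise SFSError("negative SFS entries")
        structural = canonical_mask(self.n1, self.n2).copy()
        structural[0, 0] = False
        structural[self.n1, self.n2] = False
        if (np.abs(self.counts[structural]) > 1e-9).any():
            raise SFSError("mass beyond the fold line (entries with i+j > (n1+n2)/2)")

    # -- basic queries ------------------------------------------------------

    def total(self) -> float:
        """Sum of unmasked entries (contributing segregating sites)."""
        return float(self.counts[~self.mask].sum())

    def normalized(self) -> "FoldedJointSFS":
        tot = self.total()
        if tot <= 0:
            raise SFSError("cannot normalize an empty SFS")
        c = self.counts.copy()
        c[~self.mask] /= tot
        c[self.mask] = 0.0
        return replace(self, counts=c)

    def copy(self) -> "FoldedJointSFS":
        return replace(self, counts=self.counts.copy(), mask=self.mask.copy())

    def allclose(self, other: "FoldedJointSFS", atol: float = 1e-9) -> bool:
        return (
            self.n1 == other.n1
            and self.n2 == other.n2
            and np.array_equal(self.mask, other.mask)
            and np.allclose(self.counts, other.counts, atol=atol)
        )


def sfs_total(s: FoldedJointSFS) -> float:
    """Number of contributing segregating sites (sum of unmasked entries)."""
    return s.total()


# ---------------------------------------------------------------------------
# hypergeometric projection
# ---------------------------------------------------------------------------

def _hyp_weights(c: int, a: int, m: int) -> np.ndarray:
    """P(k alternate of m drawn | a alternate among c alleles), k = 0..m."""
    k = np.arange(m + 1)
    with np.errstate(divide="ignore"):
        lg = (
            _lchoose(a, k)
            + _lchoose(c - a, m - k)
            - _lchoose(c, m)
        )
    w = np.exp(lg)
    w[(k > a) | (m - k > c - a)] = 0.0
    return w


def _lchoose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def build_folded_joint_sfs(
    g: GenotypeMatrix,
    pm: PopulationMap,
    group_a: str,
    group_b: str,
    projection: tuple[int, int],
) -> FoldedJointSFS:
    """Build the folded joint SFS of two groups at fixed projection sizes.

    Each locus's non-missing alleles are projected down to ``(n1, n2)``
    allele copies by hypergeometric expectation; loci with fewer available
    alleles than the projection in either group contribute nothing
    (projection loss).
    """
    n1, n2 = projection
    if n1 < 2 or n2 < 2:
        raise SFSError("projection sizes must be >= 2 allele copies")
    gidx = pm.group_indices(g)
    for grp in (group_a, group_b):
        if grp not in gidx:
            raise SFSError(f"group {grp!r} not present in the population map")
    ia, ib = gidx[group_a], gidx[group_b]
    Xa, Xb = g.genotypes[ia], g.genotypes[ib]
    ca = 2 * (Xa != MISSING).sum(axis=0)
    cb = 2 * (Xb != MISSING).sum(axis=0)
    aa = np.where(Xa != MISSING, Xa, 0).sum(axis=0)
    ab = np.where(Xb != MISSING, Xb, 0).sum(axis=0)

    usable = (ca >= n1) & (cb >= n2)
    if not usable.any():
        raise SFSError(
            f"projection ({n1}, {n2}) larger than available alleles at every locus"
        )
    unfolded = np.zeros((n1 + 1, n2 + 1))
    cache: dict[tuple[int, int, int], np.ndarray] = {}

    def w(c: int, a: int, m: int) -> np.ndarray:
        key = (c, a, m)
        if key not in cache:
            cache[key] = _hyp_weights(c, a, m)
        return cache[key]

    for l in np.flatnonzero(usable):
        unfolded += np.outer(w(int(ca[l]), int(aa[l]), n1), w(int(cb[l]), int(ab[l]), n2))
    folded = fold_unfolded(unfolded)
    return FoldedJointSFS(counts=folded, n1=n1, n2=n2)


def project_sfs(s: FoldedJointSFS, m1: int, m2: int) -> FoldedJointSFS:
    """Project to smaller sample sizes by entry-wise hypergeometric
    expectation, then refold.  Total mass is non-increasing (mass reaching
    the monomorphic corners is masked away)."""
    if m1 < 2 or m2 < 2:
        raise SFSError("projection sizes must be >= 2")
    if m1 > s.n1 or m2 > s.n2:
        raise SFSError(f"cannot project ({s.n1},{s.n2}) up to ({m1},{m2})")
    if m1 == s.n1 and m2 == s.n2:
        return s.copy()
    unfolded = np.zeros((m1 + 1, m2 + 1))
    for i in range(s.n1 + 1):
        wi = _hyp_weights(s.n1, i, m1)
        for j in range(s.n2 + 1):
            if s.mask[i, j] or s.counts[i, j] == 0:
                continue
            unfolded += s.counts[i, j] * np.outer(wi, _hyp_weights(s.n2, j, m2))
    folded = fold_unfolded(unfolded)
    return FoldedJointSFS(
        counts=folded, n1=m1, n2=m2,
        total_sites=s.total_sites, mutation_rate=s.mutation_rate,
    )


# ---------------------------------------------------------------------------
# serialization: fastsimcoal2 joint-SFS text layout and a TSV alternative
# ---------------------------------------------------------------------------

def write_sfs(s: FoldedJointSFS, path, format: str = "fsc2") -> Path:
    """Write in the fastsimcoal2 joint-SFS layout (rows = deme 2, columns =
    deme 1, ``d0_i`` / ``d1_j`` labels) or as a TSV with ``#`` metadata."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "fsc2":
            fh.write("1 observations\n")
            fh.write("\t" + "\t".join(f"d0_{i}" for i in range(s.n1 + 1)) + "\n")
            for j in range(s.n2 + 1):
                row = "\t".join(repr(float(s.counts[i, j])) for i in range(s.n1 + 1))
                fh.write(f"d1_{j}\t{row}\n")
        elif format == "tsv":
            fh.write(f"#n1={s.n1}\n#n2={s.n2}\n")
            if s.total_sites is not None:
                fh.write(f"#total_sites={float(s.total_sites)!r}\n")
            if s.mutation_rate is not None:
                fh.write(f"#mutation_rate={float(s.mutation_rate)!r}\n")
            fh.write("i\tj\tcount\tmasked\n")
            for i in range(s.n1 + 1):
                for j in range(s.n2 + 1):
                    fh.write(
                        f"{i}\t{j}\t{float(s.counts[i, j])!r}\t{int(s.mask[i, j])}\n"
                    )
        else:
            raise ValueError(f"unknown SFS format {format!r}")
    return path


def read_sfs(path, format: Optional[str] = None) -> FoldedJointSFS:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if format is None:
        format = "fsc2" if "observations" in first else "tsv"
    if format == "fsc2":
        with open(path) as fh:
            fh.readline()
            header = fh.readline().split()
            n1 = len(header) - 1
            rows = []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                rows.append([float(x) for x in parts[1:]])
        counts = np.array(rows).T  # rows were deme 2
        n2 = counts.shape[1] - 1
        return FoldedJointSFS(counts=counts, n1=n1, n2=n2)
    meta: dict[str, float] = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k] = float(v)
            elif line.strip() and not line.startswith("i\t"):
                body.append(line.split())
    n1, n2 = int(meta["n1"]), int(meta["n2"])
    counts = np.zeros((n1 + 1, n2 + 1))
    mask = np.zeros_like(counts, dtype=bool)
    for i, j, c, m in body:
        counts[int(i), int(j)] = float(c)
        mask[int(i), int(j)] = bool(int(m))
    return FoldedJointSFS(
        counts=counts, n1=n1, n2=n2, mask=mask,
        total_sites=meta.get("total_sites"), mutation_rate=meta.get("mutation_rate"),
    )
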