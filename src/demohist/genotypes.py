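"""Genotype matrices, population maps, and SNP extraction filters.

The pipeline's raw input is a diploid biallelic genotype matrix (alternate
allele dosage per individual and locus, with missingness) plus a map
assigning individuals to populations and populations to groups.  Filtering
mirrors reduced-representation (GBS) practice: minimum minor allele
frequency, per-population genotyping rate, maximum observed heterozygosity,
and a minimum number of populations carrying data at the locus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING: int = -1  # genotype code for a missing diploid call

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "FilterSpec",
    "FilterReport",
    "GenotypeParseError",
    "FilterError",
    "read_genotypes",
    "write_genotypes",
    "read_population_map",
    "write_population_map",
    "apply_snp_filters",
]


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed under the named standard."""


class FilterError(ValueError):
    """SNP filtering produced an unusable (empty) matrix."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotypes as alternate-allele dosage.

    ``genotypes[i, l]`` is in ``{0, 1, 2}`` (copies of the alternate
    allele) or :data:`MISSING`.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, l = self.genotypes.shape
        if n != len(self.individual_ids) or l != len(self.locus_ids):
            raise ValueError(
                f"genotype array {self.genotypes.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        if len(set(self.locus_ids)) != l:
            raise ValueError("locus ids must be unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            i, l_ = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype code {self.genotypes[i, l_]} at "
                f"({self.individual_ids[i]}, {self.locus_ids[l_]}) outside {{0,1,2,missing}}"
            )

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            locus_ids=[self.locus_ids[j] for j in keep],
            genotypes=self.genotypes[:, keep].copy(),
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in keep],
            locus_ids=list(self.locus_ids),
            genotypes=self.genotypes[keep].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class PopulationMap:
    """Assignment of individuals to populations and populations to groups."""

    individual_to_population: dict[str, str]
    population_to_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pops = set(self.individual_to_population.values())
        if self.population_to_group:
            unassigned = pops - set(self.population_to_group)
            if unassigned:
                raise ValueError(f"populations without a group: {sorted(unassigned)}")
        else:
            # groups default to the populations themselves (flat hierarchy)
            self.population_to_group = {p: p for p in pops}

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.individual_to_population.values():
            seen.setdefault(p, None)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(self.population_to_group[p], None)
        return list(seen)

    def populations_in_group(self, group: str) -> list[str]:
        return [p for p in self.populations if self.population_to_group[p] == group]

    def check_covers(self, g: GenotypeMatrix) -> None:
        missing = [i for i in g.individual_ids if i not in self.individual_to_population]
        if missing:
            raise ValueError(f"individuals without population assignment: {missing[:5]}...")

    def population_indices(self, g: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Row indices into ``g`` for each population (matrix order)."""
        self.check_covers(g)
        out: dict[str, list[int]] = {}
        for i, ind in enumerate(g.individual_ids):
            out.setdefault(self.individual_to_population[ind], []).append(i)
        return {p: np.asarray(v, dtype=int) for p, v in out.items()}

    def group_indices(self, g: GenotypeMatrix) -> dict[str, np.ndarray]:
        pops = self.population_indices(g)
        out: dict[str, list[int]] = {}
        for p, idx in pops.items():
            out.setdefault(self.population_to_group[p], []).extend(idx.tolist())
        return {grp: np.asarray(sorted(v), dtype=int) for grp, v in out.items()}


@dataclass(frozen=True)
class FilterSpec:
    """SNP retention thresholds.

    Defaults follow common GBS extraction practice: minor allele frequency
    >= 0.05, genotyping rate >= 80% of individuals within populations,
    observed heterozygosity <= 50%, data in at least five populations.
    """

    min_maf: float = 0.05
    min_genotyping_rate: float = 0.80
    max_obs_het: float = 0.50
    min_populations: int = 5

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_genotyping_rate", "max_obs_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_populations < 1:
            raise ValueError("min_populations must be >= 1")


@dataclass
class FilterReport:
    """Per-criterion removal tallies for one filtering pass.

    A locus failing several criteria is attributed to the first matching
    one in the order: (a) minor allele frequency; (b) too few populations
    meeting the genotyping rate (among loci with data in enough
    populations); (c) excess observed heterozygosity; (d) data present in
    fewer than the minimum number of populations.
    """

    n_input: int
    n_retained: int
    removed: dict[str, int]

    CRITERIA = ("maf", "genotyping_rate", "excess_heterozygosity", "min_populations")

    def __post_init__(self) -> None:
        if self.n_retained + sum(self.removed.values()) != self.n_input:
            raise ValueError("retained + removed must equal input locus count")

    def summary(self) -> str:
        lines = [f"loci in: {self.n_input}   retained: {self.n_retained}"]
        for c in self.CRITERIA:
            lines.append(f"  removed ({c}): {self.removed.get(c, 0)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _detect_format(path: Path) -> str:
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        return "vcf"
    return "table"


def read_genotypes(path, format: Optional[str] = None,
                   split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a dosage table (TSV).

    Only biallelic SNP records are turned into loci.  Multiallelic VCF
    records are skipped with a warning by default; with
    ``split_multiallelic`` each alternate allele becomes its own locus with
    dosage counted against that allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt == "vcf":
        return _read_vcf(path, split_multiallelic)
    if fmt == "table":
        return _read_table(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path, split_multiallelic: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error classes vary
        raise GenotypeParseError(f"{path}: not parseable as VCF: {exc}") from exc
    individuals = list(vcf.samples)
    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    record = 0
    try:
        for v in vcf:
            record += 1
            name = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
            if getattr(v, "ploidy", 2) != 2:
                raise GenotypeParseError(
                    f"{path}: record {record} ({name}): non-diploid call (ploidy {v.ploidy})"
                )
            if len(v.ALT) != 1:
                if not split_multiallelic:
                    log.warning("%s: record %d (%s): multiallelic, skipped", path, record, name)
                    warnings.warn(f"multiallelic record {name} skipped", stacklevel=2)
                    continue
                alleles = np.array(v.genotype.array())[:, :2]
                for ai in range(1, len(v.ALT) + 1):
                    dos = (alleles == ai).sum(axis=1).astype(np.int8)
                    dos[(alleles < 0).any(axis=1)] = MISSING
                    rows.append(dos)
                    locus_ids.append(f"{name}_alt{ai}")
                continue
            gt = v.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            dos = np.full(gt.shape, MISSING, dtype=np.int8)
            dos[gt == 0] = 0
            dos[gt == 1] = 1
            dos[gt == 3] = 2
            rows.append(dos)
            locus_ids.append(name)
    except GenotypeParseError:
        raise
    except Exception as exc:
        raise GenotypeParseError(f"{path}: malformed record at line ~{record}: {exc}") from exc
    geno = (
        np.column_stack(rows) if rows else np.zeros((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, locus_ids, geno)


def _read_table(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise GenotypeParseError(f"{path}: not parseable as a genotype table: {exc}") from exc
    geno = np.full(df.shape, MISSING, dtype=np.int8)
    if df.size == 0:
        return GenotypeMatrix(list(df.index), list(df.columns), geno)
    for code in (0, 1, 2):
        geno[df.values == str(code)] = code
    ok = df.isna().values | np.isin(df.values.astype(str), ["0", "1", "2", "NA"])
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise GenotypeParseError(
            f"{path}: line {i + 2}: bad genotype code {df.values[i, j]!r} "
            f"(individual {df.index[i]}, locus {df.columns[j]})"
        )
    return GenotypeMatrix(list(df.index), list(df.columns), geno)


def write_genotypes(g: GenotypeMatrix, path, format: Optional[str] = None) -> Path:
    """Write ``g`` as VCF (GT-only) or dosage TSV; round-trips with the reader."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "vcf":
        _write_vcf(g, path)
    elif fmt == "table":
        values = g.genotypes.astype(str).astype(object)
        values[g.genotypes == MISSING] = "NA"
        df = pd.DataFrame(values, index=g.individual_ids, columns=g.locus_ids)
        df.to_csv(path, sep="\t", index_label="individual")
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    return path


def _split_locus_id(locus: str) -> tuple[str, int, str]:
    """(chrom, pos, id-field) for a VCF row, round-trip safe."""
    if ":" in locus:
        chrom, _, pos = locus.rpartition(":")
        if pos.isdigit():
            return chrom, int(pos), "."
    return "0", 0, locus  # POS filled by caller


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=demohist\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j, locus in enumerate(g.locus_ids):
            chrom, pos, vid = _split_locus_id(locus)
            if vid != ".":
                chrom, pos = "0", j + 1
            gts = "\t".join(_GT_STRINGS[int(c)] for c in g.genotypes[:, j])
            fh.write(f"{chrom}\t{pos}\t{vid}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def read_population_map(path) -> PopulationMap:
    """Two- or three-column TSV: individual, population[, group]."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] == 1 or df.shape[1] > 3:
        raise GenotypeParseError(f"{path}: population map needs 2 or 3 columns")
    # tolerate a header row
    if df.iloc[0, 0].lower() in ("individual", "sample", "ind"):
        df = df.iloc[1:]
    ind_to_pop = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    pop_to_group: dict[str, str] = {}
    if df.shape[1] == 3:
        pop_to_group = dict(zip(df.iloc[:, 1], df.iloc[:, 2]))
    return PopulationMap(ind_to_pop, pop_to_group)


def write_population_map(pm: PopulationMap, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for ind, pop in pm.individual_to_population.items():
            fh.write(f"{ind}\t{pop}\t{pm.population_to_group[pop]}\n")
    return path


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def apply_snp_filters(
    g: GenotypeMatrix, pm: PopulationMap, spec: FilterSpec = FilterSpec()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP extraction filters and report per-criterion removals.

    A locus is retained iff (a) its whole-sample minor allele frequency is
    >= ``min_maf``, (b) at least ``min_populations`` populations each have a
    within-population genotyping rate >= ``min_genotyping_rate`` (this single
    rule also subsumes the minimum-populations criterion), and (c) its
    whole-sample observed heterozygosity is <= ``max_obs_het``.
    """
    pm.check_covers(g)
    X = g.genotypes
    nonmiss = X != MISSING
    n_nonmiss = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, X, 0).sum(axis=0)
    alleles = 2 * n_nonmiss
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(alleles > 0, alt / np.maximum(alleles, 1), np.nan)
        het = np.where(n_nonmiss > 0, (X == 1).sum(axis=0) / np.maximum(n_nonmiss, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)

    pass_a = (alleles > 0) & (maf >= spec.min_maf)
    pop_idx = pm.population_indices(g)
    n_meeting = np.zeros(g.n_loci, dtype=int)
    n_with_data = np.zeros(g.n_loci, dtype=int)
    for idx in pop_idx.values():
        rate = nonmiss[idx].mean(axis=0)
        n_meeting += rate >= spec.min_genotyping_rate
        n_with_data += nonmiss[idx].any(axis=0)
    rule_b = n_meeting >= spec.min_populations
    pass_c = het <= spec.max_obs_het

    retained = pass_a & rule_b & pass_c
    unattributed = ~retained
    removed: dict[str, int] = {}
    for crit, match in (
        ("maf", ~pass_a),
        ("genotyping_rate", ~rule_b & (n_with_data >= spec.min_populations)),
        ("excess_heterozygosity", ~pass_c),
        ("min_populations", n_with_data < spec.min_populations),
    ):
        hit = unattributed & match
        removed[crit] = int(hit.sum())
        unattributed &= ~hit
    report = FilterReport(n_input=g.n_loci, n_retained=int(retained.sum()), removed=removed)
    if report.n_retained == 0:
        raise FilterError(f"zero loci retained out of {g.n_loci}:\n{report.summary()}")
    return g.subset_loci(retained), report
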