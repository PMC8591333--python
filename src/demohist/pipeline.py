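"""End-to-end orchestration: filter -> stats -> SFS -> fit -> scale -> report.

A single :class:`RunConfig` (YAML-serializable) drives the whole analysis,
either from genotype files on disk or from a synthetic-generation block,
with every seed explicit.  Outputs are tab-separated tables mirroring the
usual per-population diversity and AMOVA layouts, the SFS in fastsimcoal
text format, a scenario fit report, scaled parameter estimates, and a
provenance log (config echo, package version, content hashes).  The SFS
and per-scenario fits are cached by config-section hash so re-running with
a changed scenario list reuses everything still valid.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__ as _pkg_version
from .genotypes import (
    FilterSpec,
    apply_snp_filters,
    read_genotypes,
    read_population_map,
    write_genotypes,
    write_population_map,
)
from .diversity import amova, diversity_table, fst_matrix
from .engine import STUDY_LAYOUT, SimulationRequest, simulate_genotype_matrix
from .inference import (
    DemographicModel,
    DemographicResults,
    ScalingSpec,
    fit_report,
    rank_models,
)
from .models import DEMO_SECEXP_PARAMS, build_demography, get_scenario
from .sfs import build_folded_joint_sfs, read_sfs, write_sfs

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class SyntheticBlock:
    """Synthetic-data generation settings (used when no input paths given)."""

    scenario: str = "SECEXP"
    params: dict = field(default_factory=lambda: dict(DEMO_SECEXP_PARAMS))
    layout: str | list = "study"
    num_loci: int = 5000
    locus_length: int = 3
    mutation_rate: float = 1.16e-7
    missingness: float = 0.1
    seed: int = 1


@dataclass
class RunConfig:
    output_dir: str = "demohist_run"
    genotypes: Optional[str] = None
    population_map: Optional[str] = None
    synthetic: Optional[SyntheticBlock] = None
    filter: Optional[dict] = field(default_factory=dict)
    amova_groups: Optional[dict] = None
    amova_permutations: int = 999
    amova_seed: int = 1
    sfs_groups: tuple[str, str] = ("NL", "ES")
    projection: tuple[int, int] = (20, 20)
    scenarios: list[str] = field(default_factory=list)
    fit_replicates: int = 10
    fit_sims: int = 2000
    fit_seed: int = 1
    clock_rate: float = 2.32e-8
    generation_time: float = 5.0

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticBlock(**self.synthetic)
        if self.genotypes is None and self.synthetic is None:
            raise ValueError("config needs input paths or a synthetic block")
        self.projection = tuple(self.projection)
        self.sfs_groups = tuple(self.sfs_groups)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("input")
def _load_input(cfg: RunConfig, out: Path):
    if cfg.genotypes is not None:
        g = read_genotypes(cfg.genotypes)
        pm = read_population_map(cfg.population_map)
        return g, pm
    syn = cfg.synthetic
    layout = STUDY_LAYOUT if syn.layout == "study" else [tuple(r) for r in syn.layout]
    dem = build_demography(syn.scenario, syn.params)
    n1 = 2 * sum(n for _, n, grp in layout if grp == "NL")
    n2 = 2 * sum(n for _, n, grp in layout if grp == "ES")
    req = SimulationRequest(
        demography=dem,
        n1=n1,
        n2=n2,
        num_loci=syn.num_loci,
        locus_length=syn.locus_length,
        mutation_rate=syn.mutation_rate,
        missingness=syn.missingness,
        seed=syn.seed,
    )
    ds = simulate_genotype_matrix(req, layout)
    write_genotypes(ds.genotypes, out / "synthetic_genotypes.vcf")
    write_population_map(ds.population_map, out / "synthetic_popmap.tsv")
    return ds.genotypes, ds.population_map


@_stage("filter")
def _filter(cfg: RunConfig, g, pm, out: Path):
    spec = FilterSpec(**(cfg.filter or {}))
    filtered, report = apply_snp_filters(g, pm, spec)
    (out / "filter_report.txt").write_text(report.summary() + "\n")
    write_genotypes(filtered, out / "filtered_genotypes.tsv", format="table")
    return filtered, report


@_stage("stats")
def _stats(cfg: RunConfig, g, pm, out: Path):
    div = diversity_table(g, pm)
    div.to_csv(out / "diversity.tsv", sep="\t")
    fst = fst_matrix(g, pm)
    fst.to_csv(out / "fst_matrix.tsv", sep="\t")
    am = amova(
        g, pm, groups=cfg.amova_groups,
        n_perm=cfg.amova_permutations, seed=cfg.amova_seed,
    )
    (out / "amova.tsv").write_text(am.table().to_csv(sep="\t"))
    (out / "amova_summary.txt").write_text(am.summary() + "\n")
    return div, am


@_stage("sfs")
def _sfs(cfg: RunConfig, g, pm, out: Path, cache: dict, provenance: dict):
    key = _hash(
        ["sfs", cfg.sfs_groups, cfg.projection, g.locus_ids[:5], g.n_loci,
         cfg.synthetic.seed if cfg.synthetic else cfg.genotypes]
    )
    path = out / "joint_sfs.tsv"
    if cache.get("sfs") == key and path.exists():
        log.info("sfs stage: cache hit, reusing %s", path)
        return read_sfs(path), key
    a, b = cfg.sfs_groups
    s = build_folded_joint_sfs(g, pm, a, b, cfg.projection)
    if cfg.synthetic is not None:
        s.total_sites = float(cfg.synthetic.num_loci * cfg.synthetic.locus_length)
        s.mutation_rate = cfg.synthetic.mutation_rate
    write_sfs(s, path, format="tsv")
    write_sfs(s, out / "joint_sfs.obs", format="fsc2")
    return s, key


@_stage("fit")
def _fits(cfg: RunConfig, obs, out: Path, cache: dict, sfs_key: str):
    results = []
    for name in cfg.scenarios:
        key = _hash([sfs_key, name, cfg.fit_replicates, cfg.fit_sims, cfg.fit_seed])
        fpath = out / f"fit_{name}.json"
        if cache.get(f"fit_{name}") == key and fpath.exists():
            log.info("fit stage: cache hit for %s", name)
            d = json.loads(fpath.read_text())
            res = DemographicResults(
                scenario=get_scenario(name), params=d["params"], llf=d["llf"],
                n_replicates=d["n_replicates"], n_sims=d["n_sims"], seed=d["seed"],
                observed=obs,
            )
        else:
            res = DemographicModel(obs, name).fit(
                n_replicates=cfg.fit_replicates, n_sims=cfg.fit_sims, seed=cfg.fit_seed
            )
            fpath.write_text(json.dumps(res.to_dict(), indent=2))
        results.append((res, key))
    return results


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all configured stages; returns a report bundle (objects + paths).

    Any stage failure aborts with the stage name and cause; previously
    written outputs remain on disk and are flagged as partial in the
    provenance log.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov_path = out / "provenance.json"
    cache: dict = {}
    if prov_path.exists():
        try:
            cache = json.loads(prov_path.read_text()).get("stage_hashes", {})
        except json.JSONDecodeError:
            cache = {}
    bundle: dict = {"output_dir": str(out)}
    provenance: dict = {
        "package": "demohist",
        "version": _pkg_version,
        "config": cfg.to_dict(),
        "stage_hashes": {},
        "complete": False,
    }
    try:
        g, pm = _load_input(cfg, out)
        g, report = _filter(cfg, g, pm, out)
        bundle["filter_report"] = report
        div, am = _stats(cfg, g, pm, out)
        bundle["diversity"] = div
        bundle["amova"] = am
        obs, sfs_key = _sfs(cfg, g, pm, out, cache, provenance)
        provenance["stage_hashes"]["sfs"] = sfs_key
        bundle["sfs"] = obs
        if cfg.scenarios:
            fits_keys = _fits(cfg, obs, out, cache, sfs_key)
            fits = [f for f, _ in fits_keys]
            for (f, key) in fits_keys:
                provenance["stage_hashes"][f"fit_{f.name}"] = key
            ranked = rank_models(fits)
            rep = fit_report(ranked)
            rep.to_csv(out / "fit_report.tsv", sep="\t")
            bundle["fits"] = ranked
            scaling = ScalingSpec(cfg.clock_rate, cfg.generation_time)
            scaled = ranked[0].scale(scaling)
            scaled.table().to_csv(out / "scaled_parameters.tsv", sep="\t", index=False)
            bundle["scaled"] = scaled
        provenance["complete"] = True
    finally:
        for p in sorted(out.iterdir()):
            if p.name != "provenance.json" and p.is_file():
                provenance.setdefault("outputs", {})[p.name] = hashlib.sha256(
                    p.read_bytes()
                ).hexdigest()[:16]
        prov_path.write_text(json.dumps(provenance, indent=2, default=str))
    bundle["provenance"] = provenance
    return bundle
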