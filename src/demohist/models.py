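"""Two-deme demographic scenarios and their parameterizations.

The system under study is a pair of population groups — a western montane
group (``NL``) and an eastern group (``ES``) — that split from a common
ancestral population and may subsequently have exchanged migrants, gone
through bottlenecks, or expanded.  Ten competing scenarios are registered,
built from the families: no isolation (NIS), isolation only (IS), isolation
with migration (MIG, one-way variant MIG1W), ancient-only migration (AMIG),
recent-only migration (RMIG), bottleneck (BOT), secondary contact (SEC),
demographic expansion (EXP), and the secondary-contact-plus-expansion
composite (SECEXP).

Times are in generations throughout this module; sizes are diploid
individuals; migration is reported as ``M = 2*N*m`` individual migrants per
generation (``N`` the receiving deme's diploid size, ``m`` the backward
per-generation migration proportion used by the coalescent machinery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np

__all__ = [
    "MigrationEpoch",
    "Bottleneck",
    "Demography",
    "ParamSpec",
    "ModelSpec",
    "SCENARIOS",
    "list_scenarios",
    "get_scenario",
    "build_demography",
    "sample_parameters",
    "DEMO_SECEXP_PARAMS",
]


class DemographyError(ValueError):
    """Raised when a demography violates its structural invariants."""


@dataclass(frozen=True)
class MigrationEpoch:
    """A time interval with constant migration between the two demes.

    ``start`` and ``end`` are measured backward from the present in
    generations (``0 <= start < end``).  Rates are backward per-generation
    proportions: ``m_nl_to_es`` is the probability that a lineage sampled in
    ES traces its parent to NL (i.e. forward migration NL -> ES), and
    symmetrically for ``m_es_to_nl``.
    """

    start: float
    end: float
    m_nl_to_es: float = 0.0
    m_es_to_nl: float = 0.0


@dataclass(frozen=True)
class Bottleneck:
    """An epoch-limited reduction of one deme to ``size`` diploids.

    The bottleneck spans ``[start, start + duration]`` backward in time.
    """

    deme: str
    size: float
    start: float
    duration: float


@dataclass(frozen=True)
class Demography:
    """Event-based description of a (possibly structured) demography.

    When ``panmictic`` is true the model is a single deme of size ``ne_nl``
    and all other structure fields must be absent; otherwise NL and ES are
    present-day demes that merge into an ancestral deme of size ``ne_anc``
    at ``t_div`` generations before present.  An optional expansion replaces
    the focal deme's present size with ``pre_expansion_size`` before
    ``expansion_onset`` (exponential growth in between).
    """

    ne_nl: float
    ne_es: Optional[float] = None
    ne_anc: Optional[float] = None
    t_div: Optional[float] = None
    panmictic: bool = False
    expansion_deme: Optional[str] = None
    pre_expansion_size: Optional[float] = None
    expansion_onset: Optional[float] = None
    migration_epochs: tuple[MigrationEpoch, ...] = ()
    bottleneck: Optional[Bottleneck] = None
    t_sec: Optional[float] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.ne_nl is None or self.ne_nl <= 0:
            raise DemographyError(f"deme size must be positive, got {self.ne_nl}")
        if self.panmictic:
            if self.t_div is not None or self.migration_epochs:
                raise DemographyError("panmictic demography cannot carry split or migration")
            return
        for name, v in (("ne_es", self.ne_es), ("ne_anc", self.ne_anc), ("t_div", self.t_div)):
            if v is None or v <= 0:
                raise DemographyError(f"{name} must be positive in a two-deme demography, got {v}")
        if self.expansion_deme is not None:
            if self.expansion_deme not in ("NL", "ES"):
                raise DemographyError(f"unknown expansion deme {self.expansion_deme!r}")
            if not self.pre_expansion_size or self.pre_expansion_size <= 0:
                raise DemographyError("expansion requires a positive pre-expansion size")
            if self.expansion_onset is None or not 0 < self.expansion_onset < self.t_div:
                raise DemographyError(
                    f"expansion onset {self.expansion_onset} must lie in (0, t_div)"
                )
        for ep in self.migration_epochs:
            if not 0 <= ep.start < ep.end:
                raise DemographyError(f"bad migration epoch times ({ep.start}, {ep.end})")
            if ep.end > self.t_div + 1e-9:
                raise DemographyError("migration epoch extends beyond the divergence time")
            if ep.m_nl_to_es < 0 or ep.m_es_to_nl < 0:
                raise DemographyError("migration proportions must be >= 0")
        starts = [ep.start for ep in self.migration_epochs]
        if starts != sorted(starts):
            raise DemographyError("migration epochs must be sorted backward in time")
        if self.bottleneck is not None:
            b = self.bottleneck
            if b.size <= 0 or b.duration <= 0 or b.start < 0:
                raise DemographyError("bottleneck size/duration must be positive")
            if b.start + b.duration > self.t_div:
                raise DemographyError("bottleneck must end before the divergence time")
        if self.t_sec is not None and not 0 < self.t_sec < self.t_div:
            raise DemographyError(f"t_sec {self.t_sec} must lie strictly inside (0, t_div)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Demography":
        d = dict(d)
        d["migration_epochs"] = tuple(
            MigrationEpoch(**ep) if isinstance(ep, dict) else ep
            for ep in d.get("migration_epochs", ())
        )
        if isinstance(d.get("bottleneck"), dict):
            d["bottleneck"] = Bottleneck(**d["bottleneck"])
        return cls(**d)


@dataclass(frozen=True)
class ParamSpec:
    """Bounds and sampling law for one free scenario parameter.

    ``log=True`` parameters are drawn log-uniformly in ``(low, high)``;
    ``log=False`` parameters (migration intensities, which must be allowed
    to reach 0) uniformly.  A parameter with ``ratio_of`` set is bounded as
    a *ratio* of its parent parameter, which guarantees event ordering
    (e.g. ``T_SEC < T_DIV``) by construction during sampling.
    """

    name: str
    low: float
    high: float
    log: bool = True
    ratio_of: Optional[str] = None

    def sample_raw(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(np.exp(rng.uniform(math.log(self.low), math.log(self.high))))
        return float(rng.uniform(self.low, self.high))


_MIG_SHIFT = 0.01  # migrants/generation; shift for the optimizer's log transform


@dataclass(frozen=True)
class ModelSpec:
    """One registered demographic scenario.

    ``builder`` maps a dict of natural parameter values to a
    :class:`Demography`.  ``focal_deme`` names the deme subjected to the
    scenario's one-sided features (expansion, bottleneck, one-way
    migration); :meth:`mirrored` swaps it, supporting either group as the
    split source without enlarging the registry.
    """

    name: str
    description: str
    params: tuple[ParamSpec, ...]
    builder: Callable[[dict, str], Demography] = field(repr=False)
    focal_deme: str = "NL"

    @property
    def k(self) -> int:
        """Number of free parameters (the AIC penalty dimension)."""
        return len(self.params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    def build(self, values: dict) -> Demography:
        missing = set(self.param_names) - set(values)
        if missing:
            raise DemographyError(f"{self.name}: missing parameter values {sorted(missing)}")
        return self.builder(values, self.focal_deme)

    def mirrored(self) -> "ModelSpec":
        other = "ES" if self.focal_deme == "NL" else "NL"
        return ModelSpec(
            name=f"{self.name}@{other}",
            description=self.description + f" (focal deme {other})",
            params=self.params,
            builder=self.builder,
            focal_deme=other,
        )

    # -- transforms between natural values and the optimizer's coordinates --

    def resolve(self, raw: dict) -> dict:
        """Turn raw draws (ratios still ratios) into natural values."""
        values: dict = {}
        for p in self.params:
            v = raw[p.name]
            if p.ratio_of is not None:
                v = v * values[p.ratio_of]
            values[p.name] = v
        return values

    def to_internal(self, values: dict) -> np.ndarray:
        x = []
        for p in self.params:
            v = values[p.name]
            if p.ratio_of is not None:
                v = v / values[p.ratio_of]
            if p.log:
                x.append(math.log10(max(v, 1e-300)))
            else:
                x.append(math.log10(v + _MIG_SHIFT))
        return np.asarray(x, dtype=float)

    def from_internal(self, x: np.ndarray) -> dict:
        raw = {}
        for p, xi in zip(self.params, x):
            if p.log:
                raw[p.name] = 10.0 ** xi
            else:
                raw[p.name] = max(10.0 ** xi - _MIG_SHIFT, 0.0)
        return self.resolve(raw)

    def internal_bounds(self) -> list[tuple[float, float]]:
        out = []
        for p in self.params:
            if p.log:
                out.append((math.log10(p.low), math.log10(p.high)))
            else:
                out.append((math.log10(p.low + _MIG_SHIFT), math.log10(p.high + _MIG_SHIFT)))
        return out

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "focal_deme": self.focal_deme,
            "k": self.k,
            "parameters": [
                {
                    "name": p.name,
                    "low": p.low,
                    "high": p.high,
                    "sampling": "log-uniform" if p.log else "uniform",
                    **({"ratio_of": p.ratio_of} if p.ratio_of else {}),
                }
                for p in self.params
            ],
        }


# ---------------------------------------------------------------------------
# parameter bound conventions (wide, FSC2-style search ranges)
# ---------------------------------------------------------------------------

def _size(name: str) -> ParamSpec:
    return ParamSpec(name, 1e2, 1e7, log=True)


def _pre_size(name: str) -> ParamSpec:
    return ParamSpec(name, 1e1, 1e6, log=True)


def _tdiv() -> ParamSpec:
    return ParamSpec("T_DIV", 1e3, 1e7, log=True)


def _ratio(name: str, parent: str, high: float = 0.95) -> ParamSpec:
    return ParamSpec(name, 1e-3, high, log=True, ratio_of=parent)


def _mig(name: str) -> ParamSpec:
    return ParamSpec(name, 0.0, 20.0, log=False)


def _m_back(migrants: float, ne_receiving: float) -> float:
    # M = 2*N*m individual migrants per generation -> backward proportion m
    return migrants / (2.0 * ne_receiving)


def _base(values: dict) -> dict:
    return dict(
        ne_nl=values["NE_NL"], ne_es=values["NE_ES"],
        ne_anc=values["NE_ANC"], t_div=values["T_DIV"],
    )


def _epoch(values: dict, start: float, end: float, focal: str,
           one_way: bool = False) -> MigrationEpoch:
    m_to_es = _m_back(values.get("M_NL_ES", 0.0), values["NE_ES"])
    m_to_nl = _m_back(values.get("M_ES_NL", 0.0), values["NE_NL"])
    if one_way:
        # migration out of the focal deme only
        if focal == "NL":
            m_to_nl = 0.0
        else:
            m_to_es = 0.0
    return MigrationEpoch(start=start, end=end, m_nl_to_es=m_to_es, m_es_to_nl=m_to_nl)


def _build_nis(values: dict, focal: str) -> Demography:
    return Demography(ne_nl=values["NE"], panmictic=True)


def _build_is(values: dict, focal: str) -> Demography:
    return Demography(**_base(values))


def _build_mig(values: dict, focal: str) -> Demography:
    b = _base(values)
    return Demography(**b, migration_epochs=(_epoch(values, 0.0, b["t_div"], focal),))


def _build_mig1w(values: dict, focal: str) -> Demography:
    b = _base(values)
    v = dict(values)
    if focal == "NL":
        v.setdefault("M_ES_NL", 0.0)
        v["M_NL_ES"] = values["M_OUT"]
    else:
        v.setdefault("M_NL_ES", 0.0)
        v["M_ES_NL"] = values["M_OUT"]
    return Demography(**b, migration_epochs=(_epoch(v, 0.0, b["t_div"], focal, one_way=True),))


def _build_amig(values: dict, focal: str) -> Demography:
    b = _base(values)
    return Demography(
        **b, migration_epochs=(_epoch(values, b["t_div"] / 2.0, b["t_div"], focal),)
    )


def _build_rmig(values: dict, focal: str) -> Demography:
    b = _base(values)
    return Demography(**b, migration_epochs=(_epoch(values, 0.0, b["t_div"] / 2.0, focal),))


def _build_sec(values: dict, focal: str) -> Demography:
    b = _base(values)
    t_sec = values["T_SEC"]
    if t_sec >= b["t_div"]:
        raise DemographyError(f"T_SEC ({t_sec}) must predate T_DIV ({b['t_div']})")
    return Demography(
        **b, t_sec=t_sec, migration_epochs=(_epoch(values, 0.0, t_sec, focal),)
    )


def _build_bot(values: dict, focal: str) -> Demography:
    b = _base(values)
    start = values["T_BOT"]
    return Demography(
        **b,
        bottleneck=Bottleneck(
            deme=focal, size=values["N_BOT"], start=start, duration=values["BOT_DUR"]
        ),
    )


def _build_exp(values: dict, focal: str) -> Demography:
    b = _base(values)
    return Demography(
        **b,
        expansion_deme=focal,
        pre_expansion_size=values["N_PRE"],
        expansion_onset=values["T_EXP"],
    )


def _build_secexp(values: dict, focal: str) -> Demography:
    b = _base(values)
    t_sec = values["T_SEC"]
    if t_sec >= b["t_div"]:
        raise DemographyError(f"T_SEC ({t_sec}) must predate T_DIV ({b['t_div']})")
    return Demography(
        **b,
        t_sec=t_sec,
        expansion_deme=focal,
        pre_expansion_size=values["N_PRE"],
        expansion_onset=t_sec,
        migration_epochs=(_epoch(values, 0.0, t_sec, focal),),
    )


_IS_PARAMS = (_size("NE_ANC"), _size("NE_NL"), _size("NE_ES"), _tdiv())

SCENARIOS: dict[str, ModelSpec] = {
    s.name: s
    for s in (
        ModelSpec(
            "NIS",
            "no isolation: a single panmictic deme, both groups sample it",
            (_size("NE"),),
            _build_nis,
        ),
        ModelSpec(
            "IS",
            "isolation only: clean split at T_DIV, no gene flow afterwards",
            _IS_PARAMS,
            _build_is,
        ),
        ModelSpec(
            "MIG",
            "isolation followed by continuous bidirectional migration",
            _IS_PARAMS + (_mig("M_NL_ES"), _mig("M_ES_NL")),
            _build_mig,
        ),
        ModelSpec(
            "MIG1W",
            "isolation followed by continuous one-way migration out of the focal deme",
            _IS_PARAMS + (_mig("M_OUT"),),
            _build_mig1w,
        ),
        ModelSpec(
            "AMIG",
            "ancient migration only: gene flow in the older half of the divergence (T_DIV/2..T_DIV)",
            _IS_PARAMS + (_mig("M_NL_ES"), _mig("M_ES_NL")),
            _build_amig,
        ),
        ModelSpec(
            "RMIG",
            "recent migration only: gene flow in the recent half of the divergence (0..T_DIV/2)",
            _IS_PARAMS + (_mig("M_NL_ES"), _mig("M_ES_NL")),
            _build_rmig,
        ),
        ModelSpec(
            "BOT",
            "isolation with an epoch-limited bottleneck in the focal deme",
            _IS_PARAMS
            + (_pre_size("N_BOT"), _ratio("T_BOT", "T_DIV", 0.5), _ratio("BOT_DUR", "T_BOT", 0.9)),
            _build_bot,
        ),
        ModelSpec(
            "SEC",
            "secondary contact: isolation, then migration resumes at a free time T_SEC",
            _IS_PARAMS + (_ratio("T_SEC", "T_DIV"), _mig("M_NL_ES"), _mig("M_ES_NL")),
            _build_sec,
        ),
        ModelSpec(
            "EXP",
            "isolation with demographic expansion of the focal deme from N_PRE at T_EXP",
            _IS_PARAMS + (_pre_size("N_PRE"), _ratio("T_EXP", "T_DIV")),
            _build_exp,
        ),
        ModelSpec(
            "SECEXP",
            "secondary contact plus expansion: migration and focal-deme growth both start at T_SEC",
            _IS_PARAMS
            + (_pre_size("N_PRE"), _ratio("T_SEC", "T_DIV"), _mig("M_NL_ES"), _mig("M_ES_NL")),
            _build_secexp,
        ),
    )
}


def list_scenarios() -> list[ModelSpec]:
    """All registered scenarios (exactly the ten compared families)."""
    return list(SCENARIOS.values())


def get_scenario(name: str) -> ModelSpec:
    base = name.split("@")[0]
    if base not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; registered: {sorted(SCENARIOS)}")
    spec = SCENARIOS[base]
    if name.endswith("@ES"):
        spec = spec.mirrored()
    return spec


def build_demography(spec: ModelSpec | str, values: dict) -> Demography:
    if isinstance(spec, str):
        spec = get_scenario(spec)
    return spec.build(values)


def sample_parameters(spec: ModelSpec | str, rng_seed: int) -> dict:
    """Draw one parameter vector from the scenario's prior bounds.

    Log-uniform for sizes/times (ratio parameters on their ratio scale, so
    ordering constraints hold by construction), uniform for migration
    intensities.  Deterministic given ``rng_seed``.
    """
    if isinstance(spec, str):
        spec = get_scenario(spec)
    rng = np.random.default_rng(rng_seed)
    raw = {p.name: p.sample_raw(rng) for p in spec.params}
    return spec.resolve(raw)


#: Demonstration parameter set for SECEXP: a deep split, near-complete
#: isolation of a small pre-expansion focal deme, recent asymmetric contact
#: and strong expansion — the regime the study system sits in.
DEMO_SECEXP_PARAMS: dict = {
    "NE_ANC": 755_955.0,
    "NE_NL": 57_495.0,
    "NE_ES": 14_955.0,
    "N_PRE": 866.0,
    "T_DIV": 319_472.0,
    "T_SEC": 20_000.0,
    "M_NL_ES": 2.14,
    "M_ES_NL": 0.33,
}
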