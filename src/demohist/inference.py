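"""Composite-likelihood fitting of demographic scenarios to a folded SFS.

The estimation strategy mirrors SFS-based coalescent inference as
practiced with fastsimcoal-class tools: for a candidate scenario, the
expected folded joint SFS is estimated by Monte-Carlo coalescent
simulation, the observed site counts are scored against it with a
multinomial composite log-likelihood, and the parameters are refined by a
multi-start bounded derivative-free search.  Scenarios are compared by
AIC = 2k - 2 lnL (natural log throughout; tools that report log10
likelihoods differ from these values by a factor ln 10, which rescales
every model identically and leaves the ranking unchanged).

When the observed spectrum knows its total site count and per-generation
mutation rate, a monomorphic class anchors the absolute scale and
population sizes and times are estimated in natural units; otherwise the
spectrum shape alone is fitted and sizes/times are identifiable only
relative to the mutation rate (the results object flags this).

The user-facing surface is the model/results pair:

>>> model = DemographicModel(observed_sfs, "SECEXP")      # doctest: +SKIP
>>> res = model.fit(n_replicates=10, n_sims=2000, seed=7) # doctest: +SKIP
>>> print(res.summary())                                  # doctest: +SKIP
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import engine
from .models import DemographyError, ModelSpec, get_scenario, sample_parameters
from .sfs import FoldedJointSFS

__all__ = [
    "composite_log_likelihood",
    "DemographicModel",
    "DemographicResults",
    "FitResult",
    "fit_model",
    "rank_models",
    "ScalingSpec",
    "ScaledParams",
    "per_generation_mutation_rate",
    "scale_to_real_units",
]

_BIG = 1e12  # penalty objective for invalid parameter combinations


class FitError(RuntimeError):
    pass


def composite_log_likelihood(
    obs: FoldedJointSFS, expected: FoldedJointSFS, p_floor: Optional[float] = None
) -> float:
    """Multinomial composite log-likelihood sum m_ij * ln p_ij.

    ``expected`` must be normalized over unmasked entries (as produced by
    :func:`demohist.engine.expected_sfs`).  Zero expected probabilities
    under observed mass are floored at ``p_floor`` (default: the floor the
    expected spectrum recommends for its Monte-Carlo resolution) so the
    likelihood stays finite under simulation sparsity.
    """
    if obs.counts.shape != expected.counts.shape or not np.array_equal(
        obs.mask, expected.mask
    ):
        raise ValueError("observed and expected SFS must share shape and mask")
    if p_floor is None:
        p_floor = expected.p_floor if expected.p_floor is not None else 1e-12
    m = obs.counts[~obs.mask]
    p = np.maximum(expected.counts[~expected.mask], p_floor)
    return float(np.sum(m * np.log(p)))


def _profiled_loglike(obs: FoldedJointSFS, expected: FoldedJointSFS) -> tuple[float, float]:
    """Composite log-likelihood with the absolute scale profiled out.

    The coalescent SFS shape is invariant under jointly rescaling all
    population sizes and times by ``c`` (with migration proportions
    scaled ``1/c``, leaving 2Nm intact); only the expected polymorphism
    probability per site moves.  When the observed spectrum carries a
    total site count and mutation rate, the monomorphic-class term is
    therefore maximized analytically: ``c*`` is chosen so the expected
    per-site SNP density matches the observed one.  Returns
    ``(log-likelihood, c*)``; without an anchor, ``c* = 1`` and the
    likelihood is the conditional (shape-only) one.
    """
    ll = composite_log_likelihood(obs, expected)
    if expected.mc_rel_var is not None:
        # first-order debias of E[ln p-hat]: without it, low-simulation
        # objectives systematically favour demographies whose genealogy
        # distribution has low variance
        m = obs.counts[~obs.mask]
        rv = np.minimum(expected.mc_rel_var[~expected.mask], 1.0)
        ll += 0.5 * float(np.sum(m * rv))
        ll -= 0.5 * obs.total() * min(expected.mc_rel_var_total, 1.0)
    if obs.total_sites is None or obs.mutation_rate is None:
        return ll, 1.0
    if expected.branch_total is None:
        raise ValueError("expected SFS lacks branch_total; cannot anchor scale")
    s = obs.total()
    t = float(obs.total_sites)
    if not 0 < s < t:
        raise FitError(f"cannot anchor scale with S = {s} SNPs over {t} sites")
    # Poisson random field over sites: S ~ Poisson(mu * c * B * T); the
    # profile maximum is at c* with expected SNP density = observed S/T
    lam_obs = s / t
    c_star = lam_obs / (obs.mutation_rate * expected.branch_total)
    ll += s * math.log(lam_obs) - s
    return ll, c_star


def _moment_anchors(obs: FoldedJointSFS) -> dict:
    """Method-of-moments anchors from the folded joint SFS.

    Within-deme and pooled per-site diversity and the between-deme
    divergence d_xy are all invariant to folding, and give closed-form
    first guesses: ``Ne ~ pi/(4 mu)`` and ``T_DIV ~ (d_xy - pi_tot)/(2 mu)``.
    Without a mutation-rate/site-count anchor the absolute scale is
    arbitrary, but the ratios (all that matter once the scale is profiled)
    are unchanged, so unit constants are substituted.
    """
    t = obs.total_sites if obs.total_sites else 1.0
    mu = obs.mutation_rate if obs.mutation_rate else 1.0
    n1, n2 = obs.n1, obs.n2
    m = obs.counts
    w = ~obs.mask
    i = np.arange(n1 + 1)[:, None] * np.ones((1, n2 + 1))
    j = np.ones((n1 + 1, 1)) * np.arange(n2 + 1)[None, :]
    k = i + j
    n = n1 + n2
    pi_nl = float((m[w] * 2 * i[w] * (n1 - i[w]) / (n1 * (n1 - 1))).sum()) / t
    pi_es = float((m[w] * 2 * j[w] * (n2 - j[w]) / (n2 * (n2 - 1))).sum()) / t
    pi_tot = float((m[w] * 2 * k[w] * (n - k[w]) / (n * (n - 1))).sum()) / t
    dxy = float((m[w] * (i[w] * (n2 - j[w]) + (n1 - i[w]) * j[w]) / (n1 * n2)).sum()) / t
    return {
        "ne_nl": pi_nl / (4 * mu),
        "ne_es": pi_es / (4 * mu),
        "ne_anc": pi_tot / (4 * mu),
        "t_div": max((dxy - pi_tot) / (2 * mu), 1e-9),
    }


def _moment_candidates(obs: FoldedJointSFS, spec: ModelSpec) -> list[dict]:
    """Deterministic starting candidates built from the moment anchors.

    A small fixed grid of multiplicative variants covers the known biases
    of the moment estimators: gene flow inflates within-deme diversity
    (down-scaled deme sizes), incomplete lineage sorting shrinks the
    apparent divergence (up-scaled T_DIV and ancestral size), and
    expansion hides the pre-expansion size (small N_PRE fractions).
    """
    a = _moment_anchors(obs)
    names = set(spec.param_names)
    out: list[dict] = []
    seen: set[tuple] = set()
    for f_nl in (1.0, 3.0):
        for f_es in (1.0, 0.07):
            for f_t in (1.0, 3.0):
                for f_pre in (0.02, 0.3):
                    # deflated deme sizes only make sense together with the
                    # gene flow that explains the diversity they shed
                    for m_in in ((1.0,) if f_es == 1.0 else (1.0, 4.0)):
                        core = {
                            "NE": a["ne_anc"],
                            "NE_ANC": a["ne_anc"] * f_t,
                            "NE_NL": a["ne_nl"] * f_nl,
                            "NE_ES": a["ne_es"] * f_es,
                            "T_DIV": a["t_div"] * f_t,
                        }
                        core["N_PRE"] = core["NE_NL"] * f_pre
                        core["N_BOT"] = core["NE_NL"] * f_pre
                        core["T_SEC"] = 0.1 * core["T_DIV"]
                        core["T_EXP"] = 0.1 * core["T_DIV"]
                        core["T_BOT"] = 0.1 * core["T_DIV"]
                        core["BOT_DUR"] = 0.5 * core["T_BOT"]
                        core["M_NL_ES"] = m_in
                        core["M_ES_NL"] = 1.0
                        core["M_OUT"] = m_in
                        values = {nm: core[nm] for nm in spec.param_names if nm in core}
                        if len(values) != len(names):
                            continue
                        for p in spec.params:
                            lo, hi = p.low, p.high
                            if p.ratio_of is not None:
                                parent = values[p.ratio_of]
                                values[p.name] = float(
                                    np.clip(values[p.name], lo * parent, hi * parent)
                                )
                            else:
                                values[p.name] = float(np.clip(values[p.name], lo, hi))
                        key = tuple(round(values[nm], 6) for nm in spec.param_names)
                        if key not in seen:
                            seen.add(key)
                            out.append(values)
    return out


def _rescale_params(spec: ModelSpec, params: dict, c: float) -> dict:
    """Apply the shape-preserving rescaling: sizes and times x c,
    migrant numbers (2Nm) unchanged."""
    out = {}
    for p in spec.params:
        v = params[p.name]
        out[p.name] = v if not p.log else v * c
        # non-log parameters are the migration intensities (2Nm), invariant
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DemographicModel:
    """A demographic scenario to be fitted to an observed folded joint SFS.

    Parameters
    ----------
    observed:
        Folded joint SFS of the two groups.  If it carries ``total_sites``
        and ``mutation_rate``, absolute sizes/times are estimable.
    scenario:
        Registered scenario name (e.g. ``"SECEXP"``, ``"IS"``) or a
        :class:`~demohist.models.ModelSpec`.
    """

    def __init__(self, observed: FoldedJointSFS, scenario: ModelSpec | str):
        self.observed = observed
        self.scenario: ModelSpec = (
            get_scenario(scenario) if isinstance(scenario, str) else scenario
        )

    @classmethod
    def from_genotypes(
        cls,
        genotypes,
        population_map,
        scenario: ModelSpec | str,
        projection: tuple[int, int],
        group_a: str = "NL",
        group_b: str = "ES",
    ) -> "DemographicModel":
        from .sfs import build_folded_joint_sfs

        obs = build_folded_joint_sfs(genotypes, population_map, group_a, group_b, projection)
        return cls(obs, scenario)

    # -- likelihood machinery ----------------------------------------------

    def loglike(self, values: dict, n_sims: int, seed: int) -> float:
        """Composite log-likelihood of one parameter vector (scale profiled
        when the observed spectrum carries a mutation-rate anchor)."""
        dem = self.scenario.build(values)
        exp = engine.expected_sfs(dem, self.observed.n1, self.observed.n2, n_sims, seed)
        ll, _ = _profiled_loglike(self.observed, exp)
        return ll

    def _working_observed(self, cap: Optional[int]) -> FoldedJointSFS:
        """Down-projected copy of the observation used during fitting.

        The projection averages neighbouring frequency classes, which
        suppresses the cell-level Monte-Carlo noise of the simulated
        expected spectrum without biasing the fit (both sides of the
        comparison are coarsened identically; by coalescent exchangeability
        simulating at the smaller sample size *is* the projected
        expectation).
        """
        from .sfs import project_sfs

        if cap is None:
            return self.observed
        m1 = min(self.observed.n1, cap)
        m2 = min(self.observed.n2, cap)
        if (m1, m2) == (self.observed.n1, self.observed.n2):
            return self.observed
        return project_sfs(self.observed, m1, m2)

    @staticmethod
    def _evaluate_on(obs: FoldedJointSFS, spec: ModelSpec, x: np.ndarray,
                     bounds: np.ndarray, n_sims: int, seed: int) -> tuple[float, float]:
        x = np.clip(x, bounds[:, 0], bounds[:, 1])
        try:
            dem = spec.build(spec.from_internal(x))
            exp = engine.expected_sfs(dem, obs.n1, obs.n2, n_sims, seed)
            return _profiled_loglike(obs, exp)
        except (DemographyError, engine.SimulationError, FitError,
                OverflowError, ValueError):
            return -_BIG, 1.0

    def fit(
        self,
        n_replicates: int = 100,
        n_sims: int = 10_000,
        seed: int = 0,
        working_cap: Optional[int] = 14,
        n_scan: int = 8,
        cycles: Optional[list[tuple[float, float, int]]] = None,
        polish_maxiter: Optional[int] = None,
        selection_factor: int = 8,
        precision_cycles: tuple = ((0.12, 5),),
    ) -> "DemographicResults":
        """Multi-start composite-likelihood maximization.

        A candidate pool — a fixed grid of method-of-moments starting
        points plus ``n_scan`` draws from the scenario's prior bounds —
        is ranked once at reduced Monte-Carlo resolution, and the
        optimizer replicates rotate over the top entries so distinct
        starting basins get refined.  Each replicate refines its start by
        cyclic per-parameter line searches (``cycles`` of ``(simulation
        fraction, bracket width, grid points)``, widths >= 1 meaning the
        full bound range) on the working-resolution spectrum, then
        polishes with a short bounded Nelder-Mead, holding one simulation
        seed fixed across evaluations (common random numbers).  One size
        parameter carries no shape information (the absolute scale is
        profiled out analytically at every evaluation) and stays fixed
        during the search; the profile scale is restored on the returned
        estimates.  Replicate endpoints are compared at the full observed
        resolution with ``selection_factor * n_sims`` simulations on a
        common seed, and the winner is refined further on that same
        high-precision surface (``precision_cycles``).  The whole fit is
        deterministic given ``seed``.
        """
        if self.observed.total() <= 0:
            raise FitError("observed SFS is empty")
        spec = self.scenario
        obs = self._working_observed(working_cap)
        bounds = np.asarray(spec.internal_bounds())
        # the first non-ratio log parameter is a pure scale carrier
        pin = next(
            (i for i, p in enumerate(spec.params) if p.log and p.ratio_of is None),
            None,
        )
        free = [i for i in range(spec.k) if i != pin]
        if cycles is None:
            cycles = [(1.0, 0.3, 5)]
        if polish_maxiter is None:
            polish_maxiter = min(10, 2 * max(len(free), 1))
        moment_xs = [
            np.clip(spec.to_internal(v), bounds[:, 0], bounds[:, 1])
            for v in _moment_candidates(self.observed, spec)
        ]

        def evaluate(x, sims, sim_seed, on=obs):
            return self._evaluate_on(on, spec, x, bounds, sims, sim_seed)

        # rank the shared candidate pool (moment grid + prior draws) once;
        # replicates then rotate over the top entries so that distinct
        # starting basins get refined rather than one greedy scan winner
        scan_ss = np.random.SeedSequence(entropy=(int(seed), 0x5CA4))
        scan_seeds = scan_ss.generate_state(1 + max(n_scan, 1)) % (2**31 - 1)
        scan_sim_seed = int(scan_seeds[0])
        scan_sims = max(100, n_sims // 2)
        pool = list(moment_xs)
        for s in scan_seeds[1:]:
            draw = sample_parameters(spec, int(s))
            pool.append(np.clip(spec.to_internal(draw), bounds[:, 0], bounds[:, 1]))
        ranked_pool = sorted(
            pool, key=lambda xd: -evaluate(xd, scan_sims, scan_sim_seed)[0]
        )
        n_rotate = min(5, len(ranked_pool))

        replicates: list[dict] = []
        endpoints: list[np.ndarray] = []
        for r in range(n_replicates):
            ss = np.random.SeedSequence(entropy=(int(seed), r))
            sim_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
            nfev = len(pool) if r == 0 else 0
            x = ranked_pool[r % n_rotate].copy()
            start = spec.from_internal(x)
            for frac, width, npts in cycles:
                sims = max(100, int(round(n_sims * frac)))
                best = evaluate(x, sims, sim_seed)[0]
                nfev += 1
                for d in free:
                    lo, hi = bounds[d]
                    if width >= 1.0:
                        grid = np.linspace(lo, hi, npts)
                    else:
                        w = (hi - lo) * width
                        grid = np.linspace(max(lo, x[d] - w), min(hi, x[d] + w), npts)
                    for gv in grid:
                        xt = x.copy()
                        xt[d] = gv
                        v = evaluate(xt, sims, sim_seed)[0]
                        nfev += 1
                        if v > best:
                            best, x = v, xt
            if free:
                sub_bounds = bounds[free]

                def sub_obj(xf):
                    xt = x.copy()
                    xt[free] = xf
                    return -evaluate(xt, n_sims, sim_seed)[0]

                res = minimize(
                    sub_obj,
                    x[free],
                    method="Nelder-Mead",
                    bounds=sub_bounds,
                    options={"maxiter": polish_maxiter, "adaptive": True,
                             "xatol": 1e-3, "fatol": 1e-3},
                )
                x[free] = np.clip(res.x, sub_bounds[:, 0], sub_bounds[:, 1])
                nfev += int(res.nfev)
            llf, c_star = evaluate(x, n_sims, sim_seed)
            endpoints.append(x)
            replicates.append(
                {
                    "replicate": r,
                    "start": start,
                    "params": _rescale_params(spec, spec.from_internal(x), c_star),
                    "scale_factor": c_star,
                    "llf": llf,
                    "n_evaluations": nfev,
                }
            )
        if all(rep["llf"] <= -_BIG / 2 for rep in replicates):
            raise FitError(f"{spec.name}: optimizer never produced a finite likelihood")

        # final selection among replicate endpoints: full observed
        # resolution, higher Monte-Carlo resolution, common seed
        selection_sims = max(n_sims, selection_factor * n_sims)
        selection_seed = int(
            np.random.SeedSequence(entropy=(int(seed), 0x5E1EC7)).generate_state(1)[0]
            % (2**31 - 1)
        )
        sel_ll = []
        for x in endpoints:
            ll, c = evaluate(x, selection_sims, selection_seed, on=self.observed)
            sel_ll.append((ll, c))
        best_i = int(np.argmax([v for v, _ in sel_ll]))
        best_ll, best_c = sel_ll[best_i]
        if best_ll <= -_BIG / 2:
            raise FitError(f"{spec.name}: no finite likelihood at selection stage")
        for rep, (ll, _) in zip(replicates, sel_ll):
            rep["selection_llf"] = ll

        # refine the winning endpoint directly on the selection surface:
        # high-precision, common-seed, full-resolution per-parameter line
        # searches; only improving moves are accepted, so this stage is
        # monotone in the reported likelihood by construction
        best_x = np.clip(endpoints[best_i], bounds[:, 0], bounds[:, 1]).copy()
        for width, npts in precision_cycles:
            for d in free:
                lo, hi = bounds[d]
                w = (hi - lo) * width
                for gv in np.linspace(
                    max(lo, best_x[d] - w), min(hi, best_x[d] + w), npts
                ):
                    xt = best_x.copy()
                    xt[d] = gv
                    ll, c = evaluate(xt, selection_sims, selection_seed, on=self.observed)
                    if ll > best_ll:
                        best_ll, best_c, best_x = ll, c, xt

        best_params = _rescale_params(spec, spec.from_internal(best_x), best_c)
        return DemographicResults(
            scenario=spec,
            params=best_params,
            llf=best_ll,
            n_replicates=n_replicates,
            n_sims=n_sims,
            seed=seed,
            replicates=replicates,
            observed=self.observed,
            selection_sims=selection_sims,
            selection_seed=selection_seed,
            working_shape=(obs.n1, obs.n2),
        )


@dataclass
class DemographicResults:
    """Estimates, likelihood and AIC for one fitted scenario."""

    scenario: ModelSpec
    params: dict[str, float]
    llf: float
    n_replicates: int
    n_sims: int
    seed: int
    observed: FoldedJointSFS
    replicates: list[dict] = field(default_factory=list, repr=False)
    delta_aic: Optional[float] = None
    selection_sims: Optional[int] = None
    selection_seed: Optional[int] = None
    working_shape: Optional[tuple[int, int]] = None

    @property
    def name(self) -> str:
        return self.scenario.name

    @property
    def k(self) -> int:
        return self.scenario.k

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    @property
    def theta_confounded(self) -> bool:
        """True when sizes/times are identifiable only relative to mu."""
        return self.observed.total_sites is None or self.observed.mutation_rate is None

    def scale(self, scaling: "ScalingSpec") -> "ScaledParams":
        return scale_to_real_units(self, scaling)

    def to_dict(self) -> dict:
        return {
            "scenario": self.name,
            "k": self.k,
            "llf": self.llf,
            "aic": self.aic,
            "delta_aic": self.delta_aic,
            "params": dict(self.params),
            "n_replicates": self.n_replicates,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "theta_confounded": self.theta_confounded,
        }

    def summary(self) -> str:
        lines = [
            f"Scenario {self.name}: {self.scenario.description}",
            f"  composite lnL = {self.llf:.3f}   k = {self.k}   AIC = {self.aic:.3f}"
            + (f"   dAIC = {self.delta_aic:.3f}" if self.delta_aic is not None else ""),
            f"  replicates = {self.n_replicates}, simulations per likelihood = {self.n_sims}, seed = {self.seed}",
        ]
        if self.theta_confounded:
            lines.append(
                "  note: no mutation-rate anchor; sizes and times are relative to mu"
            )
        for name in self.scenario.param_names:
            lines.append(f"    {name:>10s} = {self.params[name]:.6g}")
        return "\n".join(lines)

    def plot_comparison(self, ax=None):  # pragma: no cover - plotting helper
        """Observed vs. fitted expected SFS heatmaps (log scale)."""
        import matplotlib.pyplot as plt

        exp = engine.expected_sfs(
            self.scenario.build(self.params),
            self.observed.n1,
            self.observed.n2,
            self.n_sims,
            self.seed,
        )
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 4))
        for a, (s, title) in zip(
            ax, [(self.observed, "observed"), (exp, f"expected ({self.name})")]
        ):
            c = np.where(s.mask, np.nan, s.counts)
            a.imshow(np.log10(c + 1e-12).T, origin="lower")
            a.set_title(title)
            a.set_xlabel("minor count, deme 1")
            a.set_ylabel("minor count, deme 2")
        return ax


FitResult = DemographicResults  # canonical alias


def fit_model(
    spec: ModelSpec | str,
    obs: FoldedJointSFS,
    n_replicates: int = 100,
    n_sims: int = 10_000,
    seed: int = 0,
    **options,
) -> DemographicResults:
    """Fit one scenario to an observed SFS (functional wrapper)."""
    return DemographicModel(obs, spec).fit(
        n_replicates=n_replicates, n_sims=n_sims, seed=seed, **options
    )


def rank_models(fits: Sequence[DemographicResults]) -> list[DemographicResults]:
    """Order fits by ascending AIC (ties: smaller k, then name); fill dAIC.

    All fits must have been computed on the same observed spectrum.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    ref = fits[0].observed
    for f in fits[1:]:
        if (f.observed.n1, f.observed.n2) != (ref.n1, ref.n2) or not np.allclose(
            f.observed.counts, ref.counts
        ):
            raise ValueError("fits were computed on different observed spectra")
    ranked = sorted(fits, key=lambda f: (f.aic, f.k, f.name))
    best = ranked[0].aic
    for f in ranked:
        f.delta_aic = f.aic - best
    return ranked


def fit_report(fits: Sequence[DemographicResults]) -> pd.DataFrame:
    """One row per scenario: name, k, lnL, AIC, dAIC, estimates."""
    ranked = rank_models(fits)
    rows = []
    for f in ranked:
        row = {"scenario": f.name, "k": f.k, "lnL": f.llf, "AIC": f.aic,
               "dAIC": f.delta_aic}
        row.update({f"est_{k}": v for k, v in f.params.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")


# ---------------------------------------------------------------------------
# scaling to real units
# ---------------------------------------------------------------------------

def per_generation_mutation_rate(clock: float, generation_time: float) -> float:
    """Substitutions/site/generation from a yearly clock rate and a
    generation time in years (their product)."""
    if clock <= 0 or generation_time <= 0:
        raise ValueError("clock rate and generation time must be positive")
    return clock * generation_time


@dataclass(frozen=True)
class ScalingSpec:
    """Unit conversion constants: a yearly clock rate and generation time."""

    clock_rate: float  # substitutions / site / year
    generation_time: float  # years

    def __post_init__(self) -> None:
        per_generation_mutation_rate(self.clock_rate, self.generation_time)

    @property
    def mu(self) -> float:
        """Per-generation mutation rate (clock x generation time)."""
        return self.clock_rate * self.generation_time


@dataclass
class ScaledParams:
    """Parameter estimates in real units (diploids, generations, years, Ma)."""

    sizes: dict[str, float]
    times_generations: dict[str, float]
    times_years: dict[str, float]
    times_ma: dict[str, float]
    migrants_per_generation: dict[str, float]
    generation_time: float
    mu: float
    theta_confounded: bool

    def table(self) -> pd.DataFrame:
        rows = []
        for k, v in self.sizes.items():
            rows.append({"parameter": k, "value": v, "units": "diploid individuals"})
        for k, v in self.times_generations.items():
            rows.append({"parameter": k, "value": v, "units": "generations"})
            rows.append({"parameter": k, "value": self.times_years[k], "units": "years"})
            rows.append({"parameter": k, "value": self.times_ma[k], "units": "Ma"})
        for k, v in self.migrants_per_generation.items():
            rows.append({"parameter": k, "value": v, "units": "migrants/generation"})
        return pd.DataFrame(rows)


_TIME_PARAMS = {"T_DIV", "T_SEC", "T_EXP", "T_BOT", "BOT_DUR"}


def scale_to_real_units(fit: DemographicResults, s: ScalingSpec) -> ScaledParams:
    """Convert a fit's estimates into diploids, years and Ma.

    Times in generations are multiplied by the generation time; sizes are
    already diploid individuals when the observed spectrum carried a
    mutation-rate anchor, and theta-confounded otherwise (flagged).
    """
    if not all(np.isfinite(v) for v in fit.params.values()):
        raise ValueError("fit contains non-finite estimates")
    sizes, gens, migr = {}, {}, {}
    for name, v in fit.params.items():
        if name in _TIME_PARAMS:
            gens[name] = v
        elif name.startswith("M_"):
            migr[name] = v
        else:
            sizes[name] = v
    years = {k: generations_to_years(v, s.generation_time) for k, v in gens.items()}
    return ScaledParams(
        sizes=sizes,
        times_generations=gens,
        times_years=years,
        times_ma={k: v / 1e6 for k, v in years.items()},
        migrants_per_generation=migr,
        generation_time=s.generation_time,
        mu=s.mu,
        theta_confounded=fit.theta_confounded,
    )


def generations_to_years(generations: float, generation_time: float) -> float:
    if generation_time <= 0:
        raise ValueError("generation time must be positive")
    return generations * generation_time
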