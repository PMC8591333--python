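"""Minimal structured-coalescent implementation used as a validation oracle.

This is a deliberately simple, event-driven simulator for small sample
sizes, written independently of msprime so the two code paths can be
compared in tests.  It supports a single panmictic deme or two
constant-size demes with piecewise-constant migration epochs and a merger
into a constant-size ancestral deme; growth and bottlenecks are out of its
scope (the fast engine covers those).

Time is continuous in generations; a deme of ``N`` diploids coalesces a
pair of lineages at rate ``k(k-1)/2 / (2N)`` and each lineage migrates
(backward) at its epoch's per-generation proportion.
"""

from __future__ import annotations

import numpy as np

from .models import Demography
from .sfs import FoldedJointSFS, canonical_mask, fold_unfolded

__all__ = ["reference_expected_sfs"]


def _rates_at(dem: Demography, t: float) -> tuple[float, float]:
    """Backward migration rates (out of NL, out of ES) active at time t."""
    for ep in dem.migration_epochs:
        if ep.start <= t < ep.end:
            # lineages in NL move to ES at the forward ES->NL proportion
            return ep.m_es_to_nl, ep.m_nl_to_es
    return 0.0, 0.0


def _next_boundary(dem: Demography, t: float) -> float:
    bounds = [dem.t_div]
    for ep in dem.migration_epochs:
        bounds.extend((ep.start, ep.end))
    ahead = [b for b in bounds if b > t + 1e-12]
    return min(ahead) if ahead else np.inf


def _simulate_branch_afs(dem: Demography, n1: int, n2: int,
                         rng: np.random.Generator) -> np.ndarray:
    """One genealogy's branch lengths per (descendants-in-1, descendants-in-2)."""
    if dem.panmictic:
        demes = [0] * (n1 + n2)
        sizes = {0: dem.ne_nl, 1: dem.ne_nl}
        merged = True
    else:
        demes = [0] * n1 + [1] * n2
        sizes = {0: dem.ne_nl, 1: dem.ne_es}
        merged = False
    blocks = [(1, 0)] * n1 + [(0, 1)] * n2
    afs = np.zeros((n1 + 1, n2 + 1))
    t = 0.0
    while len(blocks) > 1:
        k0 = demes.count(0)
        k1 = demes.count(1)
        if merged:
            m0 = m1 = 0.0
        else:
            m0, m1 = _rates_at(dem, t)
        c0 = k0 * (k0 - 1) / 2.0 / (2.0 * sizes[0])
        c1 = k1 * (k1 - 1) / 2.0 / (2.0 * sizes[1])
        mig = k0 * m0 + k1 * m1
        total = c0 + c1 + mig
        boundary = np.inf if merged else _next_boundary(dem, t)
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        step_end = min(t + wait, boundary)
        for b in blocks:
            afs[b[0], b[1]] += step_end - t
        t = step_end
        if t >= boundary:
            if not merged and t >= dem.t_div - 1e-12:
                merged = True
                demes = [0] * len(blocks)
                sizes = {0: dem.ne_anc, 1: dem.ne_anc}
            continue
        u = rng.uniform(0, total)
        if u < c0 or u < c0 + c1:
            deme = 0 if u < c0 else 1
            idx = [i for i, d in enumerate(demes) if d == deme]
            i, j = rng.choice(len(idx), size=2, replace=False)
            a, b = idx[i], idx[j]
            merged_block = (blocks[a][0] + blocks[b][0], blocks[a][1] + blocks[b][1])
            for x in sorted((a, b), reverse=True):
                blocks.pop(x)
                demes.pop(x)
            blocks.append(merged_block)
            demes.append(deme)
        else:
            u -= c0 + c1
            if u < k0 * m0:
                idx = [i for i, d in enumerate(demes) if d == 0]
                demes[idx[rng.integers(len(idx))]] = 1
            else:
                idx = [i for i, d in enumerate(demes) if d == 1]
                demes[idx[rng.integers(len(idx))]] = 0
    return afs


def reference_expected_sfs(
    demography: Demography, n1: int, n2: int, n_sims: int, seed: int
) -> FoldedJointSFS:
    """Monte-Carlo expected folded joint SFS from the naive simulator.

    Same contract as :func:`demohist.engine.expected_sfs` (normalized over
    unmasked entries, ``branch_total`` in generations per site).
    """
    for unsupported in ("expansion_deme", "bottleneck"):
        if getattr(demography, unsupported) is not None:
            raise NotImplementedError(
                f"reference simulator does not support {unsupported}"
            )
    rng = np.random.default_rng(seed)
    unfolded = np.zeros((n1 + 1, n2 + 1))
    for _ in range(n_sims):
        unfolded += _simulate_branch_afs(demography, n1, n2, rng)
    folded = fold_unfolded(unfolded / n_sims)
    mask = canonical_mask(n1, n2)
    branch_total = float(folded[~mask].sum())
    probs = np.where(mask, 0.0, folded / branch_total)
    return FoldedJointSFS(
        counts=probs, n1=n1, n2=n2, mask=mask, branch_total=branch_total
    )
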