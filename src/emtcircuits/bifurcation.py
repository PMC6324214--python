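"""SNAIL bifurcation diagrams: branches, phases, and the hybrid-region width.

A sweep walks a monotone SNAIL grid, finds all steady states at each grid
point (fresh log-spaced multistarts plus warm starts carried over from the
previous point), links states across neighbouring points into branches by
nearest-neighbour matching in log-state space, and segments the SNAIL axis
into *phases* — maximal intervals sharing the same set of coexisting stable
phenotypes, e.g. ``{E}``, ``{E, M}``, ``{E, E/M, M}``, ``{E/M, M}``, ``{M}``.

Phenotypes are assigned by branch identity: a branch is labeled where its
ZEB1-mRNA level falls in an unambiguous band (< 150 E, 200-500 hybrid,
> 600 M) and the label is inherited along the branch through the unlabeled
gaps.  The *hybrid-region width* is the total SNAIL length over which a
stable hybrid state exists — the readout of the sensitivity analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circuit import RegulatoryCircuit
from .kinetics import KineticParameterSet
from .model import build_rhs, species_scales
from .presets import ZEB_MRNA
from .steady import (
    SteadyState,
    _merit,
    batched_jacobian,
    classify_phenotype,
    classify_phenotype_strict,
    dedup_states,
    integrate_to_steady,
    log_spaced_starts,
    newton_refine,
)

logger = logging.getLogger(__name__)

#: ln-space distance below which roots at neighbouring SNAIL values are the
#: same branch
BRANCH_MATCH_TOL = 0.5


@dataclass
class Branch:
    """One connected family of steady states across the SNAIL grid."""

    branch_id: int
    grid_indices: list[int] = field(default_factory=list)
    states: list[SteadyState] = field(default_factory=list)

    def zeb_levels(self, zeb_index: int) -> np.ndarray:
        return np.array([s.state[zeb_index] for s in self.states])


@dataclass
class Phase:
    """A maximal SNAIL interval with a fixed set of stable phenotypes."""

    snail_min: float
    snail_max: float
    phenotypes: frozenset

    @property
    def width(self) -> float:
        return self.snail_max - self.snail_min

    @property
    def label(self) -> str:
        order = {"E": 0, "hybrid": 1, "M": 2}
        names = sorted(self.phenotypes, key=lambda p: order.get(p, 3))
        return "{" + ",".join("E/M" if n == "hybrid" else n for n in names) + "}"


@dataclass
class BifurcationDiagram:
    """Steady-state branches over a SNAIL grid plus the phase segmentation."""

    snail_grid: np.ndarray
    states: list[list[SteadyState]]
    branches: list[Branch]
    phases: list[Phase]
    zeb_index: int
    species_names: list[str]

    @property
    def phase_sequence(self) -> list[frozenset]:
        return [p.phenotypes for p in self.phases]

    def phase_labels(self) -> list[str]:
        return [p.label for p in self.phases]

    def stable_phenotypes_at(self, i: int) -> frozenset:
        return frozenset(s.phenotype for s in self.states[i] if s.stable)

    def branch_of(self, i: int, state: SteadyState) -> Optional[int]:
        for b in self.branches:
            for gi, s in zip(b.grid_indices, b.states):
                if gi == i and s is state:
                    return b.branch_id
        return None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: snail, branch_id, levels, stable, phenotype, phase."""
        phase_label = {}
        for p in self.phases:
            for i, s in enumerate(self.snail_grid):
                if p.snail_min <= s <= p.snail_max and i not in phase_label:
                    phase_label[i] = p.label
        rows = []
        for b in self.branches:
            for gi, st in zip(b.grid_indices, b.states):
                row = {
                    "snail": self.snail_grid[gi],
                    "branch_id": b.branch_id,
                    **{n: st.state[j] for j, n in enumerate(self.species_names)},
                    "stable": st.stable,
                    "phenotype": st.phenotype,
                    "phase": phase_label.get(gi, ""),
                }
                rows.append(row)
        return pd.DataFrame(rows).sort_values(["snail", "branch_id"]).reset_index(drop=True)


def _roots_at(rhs, scales, fresh: int, warm: Optional[np.ndarray],
              dedup_tol: float, seed: int, pre_integrate: bool = True,
              t_pre: float = 60.0, dt_pre: float = 0.5,
              tol: float = 1e-9) -> list[SteadyState]:
    """Steady states from ``fresh`` multistarts plus optional warm seeds."""
    degradation = rhs.degradation
    pools = []
    if warm is not None and len(warm):
        pools.append(np.atleast_2d(warm))
    if fresh > 0:
        rng = np.random.default_rng(seed)
        starts = log_spaced_starts(scales, fresh, rng)
        pools.append(starts)
        if pre_integrate:
            relaxed, _ = integrate_to_steady(rhs, starts, t_max=t_pre, dt=dt_pre,
                                             degradation=degradation, scales=scales)
            pools.append(relaxed)
    if not pools:
        return []
    X0 = np.vstack(pools)
    X, conv, _ = newton_refine(rhs, X0, scales, degradation, tol=tol)
    X = X[conv & np.all(np.isfinite(X), axis=-1)]
    if len(X) == 0:
        return []
    X = dedup_states(X, scales, tol=dedup_tol)
    X = X[np.lexsort(X.T[::-1])]
    J = batched_jacobian(rhs, X, scales)
    res = _merit(rhs(X), X, degradation, scales)
    out = []
    for x, Ji, ri in zip(X, J, res):
        lead = float(np.max(np.linalg.eigvals(Ji).real))
        out.append(SteadyState(state=x, stable=bool(lead < 0.0),
                               leading_eigenvalue=lead,
                               residual=float(ri)))
    return out


def _assign_branches(snail_grid, states_per_point, scales) -> list[Branch]:
    """Link roots across neighbouring grid points into branches.

    Greedy nearest-neighbour matching in log-state space; equidistant
    candidates are broken deterministically in favour of the lowest first
    coordinate (lowest-ZEB-branch-first) with a logged warning.
    """
    shift = 1e-9 * scales + 1e-30
    branches: list[Branch] = []
    active: list[Branch] = []
    next_id = 0
    for i, roots in enumerate(states_per_point):
        taken_roots: set[int] = set()
        taken_branches: set[int] = set()
        if active and roots:
            prev = np.array([np.log(b.states[-1].state + shift) for b in active])
            cur = np.array([np.log(s.state + shift) for s in roots])
            dist = np.max(np.abs(prev[:, None, :] - cur[None, :, :]), axis=-1)
            pairs = sorted(
                ((dist[a, r], r, a) for a in range(len(active)) for r in range(len(roots))),
                key=lambda t: (t[0], t[1], t[2]),
            )
            last_cost = None
            for cost, r, a in pairs:
                if cost > BRANCH_MATCH_TOL:
                    break
                if r in taken_roots or a in taken_branches:
                    continue
                if last_cost is not None and cost == last_cost:
                    logger.warning(
                        "branch-matching tie at snail=%g broken toward the "
                        "lowest branch", snail_grid[i])
                last_cost = cost
                active[a].grid_indices.append(i)
                active[a].states.append(roots[r])
                taken_roots.add(r)
                taken_branches.add(a)
        survivors = [b for j, b in enumerate(active) if j in taken_branches]
        for r, s in enumerate(roots):
            if r not in taken_roots:
                b = Branch(branch_id=next_id, grid_indices=[i], states=[s])
                next_id += 1
                branches.append(b)
                survivors.append(b)
        active = survivors
    return branches


def _label_branches(branches: list[Branch], zeb_index: int) -> None:
    """Phenotype by branch identity: unambiguous bands label the branch and
    the label is inherited across the 150-200 / 500-600 molecule gaps."""
    for b in branches:
        z = b.zeb_levels(zeb_index)
        strict = [classify_phenotype_strict(v) for v in z]
        known = [j for j, lab in enumerate(strict) if lab is not None]
        for j, st in enumerate(b.states):
            if strict[j] is not None:
                st.phenotype = strict[j]
            elif known:
                nearest = min(known, key=lambda kk: (abs(kk - j), kk))
                st.phenotype = strict[nearest]
            else:
                st.phenotype = classify_phenotype(z[j])


def _segment_phases(snail_grid, states_per_point) -> list[Phase]:
    """Merge grid points with equal stable-phenotype sets into intervals.

    Boundaries fall halfway between neighbouring grid points; the phases
    partition [grid[0], grid[-1]] with no gaps or overlaps.
    """
    sets = [frozenset(s.phenotype for s in roots if s.stable) for roots in states_per_point]
    phases: list[Phase] = []
    start = snail_grid[0]
    for i in range(1, len(snail_grid) + 1):
        if i == len(snail_grid) or sets[i] != sets[i - 1]:
            end = snail_grid[-1] if i == len(snail_grid) else 0.5 * (snail_grid[i - 1] + snail_grid[i])
            phases.append(Phase(float(start), float(end), sets[i - 1]))
            start = end
    return phases


def sweep_bifurcation(
    circuit: RegulatoryCircuit,
    params: KineticParameterSet,
    snail_grid: Sequence[float],
    n_starts: int = 24,
    n_starts_first: int = 96,
    dedup_tol: float = 1e-3,
    seed: int = 0,
    warm_states: Optional[list[Optional[np.ndarray]]] = None,
    pre_integrate: bool = True,
    zeb_name: str = ZEB_MRNA,
) -> BifurcationDiagram:
    """Build the bifurcation diagram of ``circuit`` along a monotone SNAIL grid.

    ``warm_states`` optionally supplies extra per-grid-point seed states (used
    by the sensitivity scan, which warm-starts every perturbed diagram from
    the baseline branches and can then skip fresh multistarts by passing
    ``n_starts=0``).
    """
    snail_grid = np.asarray(snail_grid, dtype=float)
    if len(snail_grid) < 2 or not (np.all(np.diff(snail_grid) > 0) or np.all(np.diff(snail_grid) < 0)):
        raise ValueError("snail_grid must be monotone with at least 2 points")
    scales = species_scales(circuit, params)
    zeb_index = circuit.index(zeb_name)

    states_per_point: list[list[SteadyState]] = []
    prev_roots: Optional[np.ndarray] = None
    for i, S in enumerate(snail_grid):
        rhs = build_rhs(circuit, params, snail=float(S))
        warm_list = []
        if prev_roots is not None and len(prev_roots):
            warm_list.append(prev_roots)
        if warm_states is not None and warm_states[i] is not None and len(warm_states[i]):
            warm_list.append(np.atleast_2d(warm_states[i]))
        warm = np.vstack(warm_list) if warm_list else None
        fresh = n_starts_first if (i == 0 and n_starts > 0) else n_starts
        roots = _roots_at(rhs, scales, fresh=fresh, warm=warm, dedup_tol=dedup_tol,
                          seed=seed + i, pre_integrate=pre_integrate)
        if not roots:
            warnings.warn(f"no steady state found at snail={S:g}", stacklevel=2)
        states_per_point.append(roots)
        prev_roots = np.array([s.state for s in roots]) if roots else prev_roots

    branches = _assign_branches(snail_grid, states_per_point, scales)
    _label_branches(branches, zeb_index)
    phases = _segment_phases(snail_grid, states_per_point)
    return BifurcationDiagram(
        snail_grid=snail_grid,
        states=states_per_point,
        branches=branches,
        phases=phases,
        zeb_index=zeb_index,
        species_names=circuit.species_names,
    )


def hybrid_region_width(diagram: BifurcationDiagram) -> float:
    """Total SNAIL length on which a stable hybrid E/M state exists."""
    return float(sum(p.width for p in diagram.phases if "hybrid" in p.phenotypes))


def refine_saddle_node(
    circuit: RegulatoryCircuit,
    params: KineticParameterSet,
    snail_exists: float,
    snail_missing: float,
    state: np.ndarray,
    rel_tol: float = 1e-4,
    match_tol: float = BRANCH_MATCH_TOL,
) -> float:
    """Bisect on SNAIL for the fold where a branch (seeded by ``state``) ends.

    ``snail_exists`` must carry the branch and ``snail_missing`` must not;
    the bracket is narrowed to ``rel_tol * |snail_missing - snail_exists|``.
    """
    scales = species_scales(circuit, params)
    shift = 1e-9 * scales + 1e-30
    x = np.asarray(state, dtype=float)
    width = abs(snail_missing - snail_exists)
    lo, hi = snail_exists, snail_missing
    while abs(hi - lo) > rel_tol * width:
        mid = 0.5 * (lo + hi)
        rhs = build_rhs(circuit, params, snail=float(mid))
        X, conv, _ = newton_refine(rhs, x[None, :], scales, rhs.degradation)
        near = conv[0] and np.max(np.abs(np.log(X[0] + shift) - np.log(x + shift))) < match_tol
        if near:
            lo = mid
            x = X[0]
        else:
            hi = mid
    return 0.5 * (lo + hi)


def quasistatic_sweep(
    circuit: RegulatoryCircuit,
    params: KineticParameterSet,
    snail_grid: Sequence[float],
    x0: np.ndarray,
    t_hold: float = 300.0,
    dt: float = 0.25,
) -> np.ndarray:
    """Adiabatically ramp SNAIL along ``snail_grid`` (either direction),
    relaxing the state at each level; returns the visited states.

    Forward and backward sweeps through a multistable region land on
    different branches (hysteresis).
    """
    x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()
    out = np.empty((len(snail_grid), x.shape[1]))
    scales = species_scales(circuit, params)
    for i, S in enumerate(np.asarray(snail_grid, dtype=float)):
        rhs = build_rhs(circuit, params, snail=float(S))
        x, _ = integrate_to_steady(rhs, x, t_max=t_hold, dt=dt)
        Xn, conv, _ = newton_refine(rhs, x, scales, rhs.degradation)
        if conv[0]:
            x = Xn
        out[i] = x[0]
    return out
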