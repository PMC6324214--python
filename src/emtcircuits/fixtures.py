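"""Small circuits with independently computable steady-state structure.

These fixtures validate the numerics (root finding, stability, bifurcation
machinery) against answers obtainable without the multistart Newton solver:
closed forms for the birth-death motif, and a brute-force oracle — dense-grid
initial conditions integrated to convergence, endpoints clustered — for the
toggle-switch and self-activation motifs.  They are numerical test articles,
not biological claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .circuit import RegulatoryCircuit, RegulatoryEdge, Species
from .kinetics import KineticParameterSet, _hill_factor
from .steady import dedup_states, integrate_to_steady


@dataclass
class FixtureSpec:
    """A fixture circuit plus its independently known steady-state structure.

    ``expected`` entries are either closed-form (``provenance='closed-form'``)
    or produced by :func:`brute_force_steady_states` /
    :func:`enumerate_roots_1d` (``provenance='brute-force'``).
    """

    name: str
    circuit: RegulatoryCircuit
    params: KineticParameterSet
    expected: dict = field(default_factory=dict)
    provenance: str = "closed-form"


@dataclass
class BruteForceResult:
    """Stable states from dense-grid integration, plus convergence bookkeeping."""

    states: np.ndarray          # (n_clusters, d), one row per attractor
    n_nonconverged: int
    n_trajectories: int


def make_birth_death(g: float = 20.0, k: float = 0.1) -> FixtureSpec:
    """One unregulated species: unique stable state at g/k, eigenvalue -k."""
    if g < 0 or k <= 0:
        raise ValueError("need g >= 0 and k > 0")
    circuit = RegulatoryCircuit(
        species=[Species("X", "protein")], edges=[], name="birth_death"
    )
    params = KineticParameterSet({"g_X": g, "k_X": k})
    return FixtureSpec(
        name="birth_death",
        circuit=circuit,
        params=params,
        expected={"stable_states": [[g / k]], "n_stable": 1, "n_unstable": 0,
                  "eigenvalue": -k},
        provenance="closed-form",
    )


def make_toggle(symmetric: bool = True, inhibition_fold: float = 0.1,
                g: float = 50.0, k: float = 0.1, threshold: float = 250.0,
                coefficient: int = 4) -> FixtureSpec:
    """Two mutually inhibiting genes (shifted-Hill toggle switch).

    The symmetric strong-inhibition toggle has two mirror-image stable states
    and one unstable state on the diagonal; with ``inhibition_fold = 1`` the
    regulation is neutral and the unique stable state is ``(g/k, g/k)``; weak
    inhibition below the pitchfork leaves a single stable state.
    """
    gB = g if symmetric else 1.1 * g
    circuit = RegulatoryCircuit(
        species=[Species("A", "protein"), Species("B", "protein")],
        edges=[
            RegulatoryEdge("A", "B", "inhibition"),
            RegulatoryEdge("B", "A", "inhibition"),
        ],
        name="toggle",
    )
    params = KineticParameterSet({
        "g_A": g, "g_B": gB, "k_A": k, "k_B": k,
        "h_A_B_X0": threshold, "h_A_B_n": coefficient, "h_A_B_lam": inhibition_fold,
        "h_B_A_X0": threshold, "h_B_A_n": coefficient, "h_B_A_lam": inhibition_fold,
    })
    if inhibition_fold == 1.0:
        expected = {"stable_states": [[g / k, gB / k]], "n_stable": 1, "n_unstable": 0}
        prov = "closed-form"
    elif symmetric and inhibition_fold <= 0.2:
        expected = {"n_stable": 2, "n_unstable": 1, "mirror_symmetric": True}
        prov = "brute-force"
    else:
        expected = {}
        prov = "brute-force"
    return FixtureSpec("toggle", circuit, params, expected, prov)


def make_self_activation(g: float = 10.0, k: float = 0.1, threshold: float = 400.0,
                         coefficient: int = 6, fold: float = 8.0) -> FixtureSpec:
    """One self-activating gene; bistable with hysteresis at the defaults.

    With ``fold = 1`` the motif is monostable at g/k for every production
    rate.  Saddle-node locations under variation of ``g`` come from the 1-D
    oracle (:func:`enumerate_roots_1d` + bisection on the root count).
    """
    circuit = RegulatoryCircuit(
        species=[Species("X", "protein")],
        edges=[RegulatoryEdge("X", "X", "activation" if fold > 1 else "inhibition")],
        name="self_activation",
    )
    params = KineticParameterSet({
        "g_X": g, "k_X": k,
        "h_X_X_X0": threshold, "h_X_X_n": coefficient, "h_X_X_lam": fold,
    })
    expected = {"n_stable": 1, "n_unstable": 0} if fold == 1.0 else {}
    return FixtureSpec("self_activation", circuit, params, expected,
                       "closed-form" if fold == 1.0 else "brute-force")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_steady_states(
    rhs,
    bounds: Sequence[tuple[float, float]],
    grid_density: int = 20,
    t_max: Optional[float] = None,
    dt: Optional[float] = None,
    conv_tol: float = 1e-6,
    merge_tol: float = 1e-2,
    scales: Optional[np.ndarray] = None,
) -> BruteForceResult:
    """Stable states by integrating from a dense grid of initial conditions.

    Every grid point is relaxed to ``t_max`` (default ``200 / min(k)``);
    endpoints with relative residual below ``conv_tol`` are clustered with a
    log-space merge radius ``merge_tol``.  This is the independent oracle the
    Newton multistart solver is validated against.
    """
    bounds = [tuple(map(float, b)) for b in bounds]
    d = len(bounds)
    axes = [np.linspace(lo, hi, grid_density) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    X0 = np.stack([m.ravel() for m in mesh], axis=-1)
    degradation = getattr(rhs, "degradation", np.ones(d))
    if t_max is None:
        t_max = 200.0 / float(np.min(degradation))
    if dt is None:
        dt = 0.2 / float(np.max(degradation))
    if scales is None:
        scales = np.array([max(abs(hi), 1.0) for _, hi in bounds])
    X, converged = integrate_to_steady(rhs, X0, t_max=t_max, dt=dt,
                                       degradation=degradation, scales=scales,
                                       tol=conv_tol)
    good = X[converged]
    clusters = dedup_states(good, scales, tol=merge_tol) if len(good) else good
    return BruteForceResult(
        states=clusters,
        n_nonconverged=int(np.sum(~converged)),
        n_trajectories=len(X0),
    )


def enumerate_roots_1d(scalar_rate, x_max: float, n_grid: int = 20001,
                       refine_tol: float = 1e-12) -> np.ndarray:
    """All roots of a scalar rate function on [0, x_max] by sign-change scan
    plus bisection refinement (the 1-D fixture oracle)."""
    x = np.linspace(0.0, x_max, n_grid)
    r = np.asarray(scalar_rate(x))
    roots = [float(x[i]) for i in np.flatnonzero(r == 0.0)]
    sign_change = np.flatnonzero(np.sign(r[:-1]) * np.sign(r[1:]) < 0)
    for i in sign_change:
        lo, hi = x[i], x[i + 1]
        flo = float(r[i])
        while hi - lo > refine_tol * max(1.0, hi):
            mid = 0.5 * (lo + hi)
            fm = float(scalar_rate(mid))
            if fm == 0.0:
                lo = hi = mid
            elif (fm > 0) == (flo > 0):
                lo, flo = mid, fm
            else:
                hi = mid
        roots.append(0.5 * (lo + hi))
    return np.array(sorted(roots))


def self_activation_rate(params: KineticParameterSet):
    """Scalar rate ``g*H(x) - k*x`` of the self-activation fixture."""
    g, k = params["g_X"], params["k_X"]
    X0, n, lam = params["h_X_X_X0"], params["h_X_X_n"], params["h_X_X_lam"]
    return lambda x: g * _hill_factor(np.asarray(x, dtype=float), X0, n, lam) - k * np.asarray(x, dtype=float)


def saddle_node_brackets(
    fixture: FixtureSpec,
    g_low: float = 1.0,
    g_high: float = 60.0,
    rel_tol: float = 1e-6,
    x_max_factor: float = 3.0,
) -> tuple[float, float]:
    """Bracket both saddle-node production rates of the self-activation motif.

    Bisection on the root count of the scalar rate function: below ``g_sn1``
    and above ``g_sn2`` the motif is monostable, in between it is bistable
    (3 roots).  Returns ``(g_sn1, g_sn2)`` to relative tolerance ``rel_tol``.
    """
    params = fixture.params
    k = params["k_X"]
    lam = params["h_X_X_lam"]

    def n_roots(g: float) -> int:
        p = params.copy()
        p["g_X"] = g
        rate = self_activation_rate(p)
        x_max = x_max_factor * g * max(lam, 1.0) / k
        # dense scan: near a fold the paired roots are close together
        return len(enumerate_roots_1d(rate, x_max, n_grid=200_001, refine_tol=1e-9))

    def bisect(lo: float, hi: float, want_three_at_hi: bool) -> float:
        while hi - lo > rel_tol * hi:
            mid = 0.5 * (lo + hi)
            if (n_roots(mid) >= 3) == want_three_at_hi:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    g_mid = None
    for g in np.linspace(g_low, g_high, 25):
        if n_roots(float(g)) >= 3:
            g_mid = float(g)
            break
    if g_mid is None:
        raise ValueError("no bistable window found in [g_low, g_high]")
    g_sn1 = bisect(g_low, g_mid, want_three_at_hi=True)
    g_sn2 = bisect(g_mid, g_high, want_three_at_hi=False)
    return g_sn1, g_sn2


def saddle_node_fold_condition(fixture: FixtureSpec, x_max_factor: float = 3.0) -> tuple[float, float]:
    """Saddle-node production rates from the analytic fold condition.

    Along the root curve ``g(x) = k*x / H(x)``, folds are the extrema of
    ``g``, i.e. roots of ``psi(x) = H(x) - x*H'(x)`` with the shifted-Hill
    derivative taken analytically.  Independent of the root-count bisection
    in :func:`saddle_node_brackets`; returns ``(g_lower, g_upper)``.
    """
    params = fixture.params
    k = params["k_X"]
    X0, n, lam = params["h_X_X_X0"], params["h_X_X_n"], params["h_X_X_lam"]

    def psi(x):
        x = np.asarray(x, dtype=float)
        u = (np.maximum(x, 1e-300) / X0) ** n
        H = (1.0 + lam * u) / (1.0 + u)
        dH_dx = (lam - 1.0) * n * u / (np.maximum(x, 1e-300) * (1.0 + u) ** 2)
        return H - x * dH_dx

    x_max = x_max_factor * params["g_X"] * max(lam, 1.0) / k * 10.0
    xs = enumerate_roots_1d(psi, x_max, n_grid=200_001, refine_tol=1e-12)
    xs = xs[xs > 0]
    if len(xs) < 2:
        raise ValueError("fold condition has fewer than two roots: monostable motif")
    u = (xs / X0) ** n
    g_at = k * xs / ((1.0 + lam * u) / (1.0 + u))
    return float(np.min(g_at)), float(np.max(g_at))
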