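"""Steady states of a circuit: multistart root finding, stability, phenotype.

The solver refines many initial points at once: states are stacked into an
``(n_starts, n_species)`` array, Jacobians come from central finite
differences, and a damped (backtracking) Newton step with projection onto the
nonnegative orthant is applied to the whole batch per iteration.  Converged
rows are deduplicated in log-space and classified by the sign of the leading
Jacobian eigenvalue.

Phenotypes follow the ZEB1-mRNA readout of the epithelial-mesenchymal model:
below 150 molecules epithelial (E), above 600 mesenchymal (M), the
~200-500 band hybrid E/M.  :func:`classify_phenotype` maps the unlabeled gaps
(150-200, 500-600) to hybrid; bifurcation diagrams instead resolve gaps by
branch identity (see :mod:`emtcircuits.bifurcation`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

#: ZEB1-mRNA phenotype thresholds (molecules): E below, M above.
E_THRESHOLD = 150.0
M_THRESHOLD = 600.0
#: printed hybrid band; levels between the bands are threshold-ambiguous
HYBRID_RANGE = (200.0, 500.0)

PHENOTYPES = ("E", "hybrid", "M")


@dataclass
class SteadyState:
    """A fixed point of the circuit ODEs with stability and phenotype."""

    state: np.ndarray
    stable: bool
    leading_eigenvalue: float  # largest real part of Jacobian eigenvalues, 1/h
    residual: float
    phenotype: Optional[str] = None

    def level(self, circuit, name: str) -> float:
        return float(self.state[circuit.index(name)])


def classify_phenotype(state, zeb_index: Optional[int] = None,
                       e_threshold: float = E_THRESHOLD,
                       m_threshold: float = M_THRESHOLD) -> str:
    """Label a state E / hybrid / M from its ZEB1-mRNA level.

    ``state`` may be the ZEB1-mRNA level itself or a full state vector with
    ``zeb_index`` pointing at the ZEB1-mRNA coordinate.
    """
    z = float(np.asarray(state).ravel()[zeb_index]) if zeb_index is not None else float(state)
    if z < e_threshold:
        return "E"
    if z > m_threshold:
        return "M"
    return "hybrid"


def classify_phenotype_strict(zeb_mrna: float) -> Optional[str]:
    """As :func:`classify_phenotype` but returns ``None`` in the unlabeled
    150-200 and 500-600 molecule gaps (resolved by branch identity)."""
    if zeb_mrna < E_THRESHOLD:
        return "E"
    if zeb_mrna > M_THRESHOLD:
        return "M"
    if HYBRID_RANGE[0] <= zeb_mrna <= HYBRID_RANGE[1]:
        return "hybrid"
    return None


# ---------------------------------------------------------------------------
# batched numerics
# ---------------------------------------------------------------------------

def batched_jacobian(rhs, X: np.ndarray, scales: np.ndarray,
                     scheme: str = "central",
                     F0: Optional[np.ndarray] = None) -> np.ndarray:
    """Finite-difference Jacobians for a batch of states (N, d).

    ``central`` (default) is used for stability classification; the cheaper
    ``forward`` scheme (reusing ``F0 = rhs(X)``) drives Newton steps.
    """
    X = np.atleast_2d(X)
    N, d = X.shape
    J = np.empty((N, d, d))
    h = 1e-6 * (np.abs(X) + 1e-6 * scales[None, :] + 1e-12)
    if scheme == "forward":
        if F0 is None:
            F0 = rhs(X)
        for j in range(d):
            Xp = X.copy()
            Xp[:, j] += h[:, j]
            J[:, :, j] = (rhs(Xp) - F0) / h[:, j][:, None]
        return J
    for j in range(d):
        Xp = X.copy()
        Xm = X.copy()
        Xp[:, j] += h[:, j]
        Xm[:, j] = np.maximum(Xm[:, j] - h[:, j], 0.0)
        dx = Xp[:, j] - Xm[:, j]
        J[:, :, j] = (rhs(Xp) - rhs(Xm)) / dx[:, None]
    return J


def _residual_weights(X: np.ndarray, degradation: np.ndarray,
                      scales: np.ndarray) -> np.ndarray:
    """Per-component residual reference ``k_i * (|x_i| + scale_i)``.

    Species levels span orders of magnitude, so residuals are judged relative
    to each species' own turnover rate rather than a global norm.
    """
    return degradation[None, :] * (np.abs(X) + scales[None, :]) + 1e-300


def _merit(F: np.ndarray, X: np.ndarray, degradation: np.ndarray,
           scales: np.ndarray) -> np.ndarray:
    return np.max(np.abs(F) / _residual_weights(X, degradation, scales), axis=-1)


def newton_refine(rhs, X0: np.ndarray, scales: np.ndarray,
                  degradation: Optional[np.ndarray] = None,
                  tol: float = 1e-9, max_iter: int = 80):
    """Damped Newton on a batch of starts; returns (X, converged, residual).

    Convergence: ``|f_i(x)| <= tol * k_i * (|x_i| + scale_i)`` for every
    component (a per-species relative residual).  Iterates are projected onto
    the nonnegative orthant.
    """
    X = np.array(np.atleast_2d(X0), dtype=float)
    N, d = X.shape
    if degradation is None:
        degradation = getattr(rhs, "degradation", np.ones(d))
    settled = np.zeros(N, dtype=bool)  # converged or stalled rows
    eye = np.eye(d)[None, :, :]
    for _ in range(max_iter):
        F = rhs(X)
        fnorm = _merit(F, X, degradation, scales)
        settled |= np.isfinite(fnorm) & (fnorm <= tol)
        settled |= ~np.isfinite(fnorm)
        active = ~settled
        if not np.any(active):
            break
        Xa, Fa = X[active], F[active]
        J = batched_jacobian(rhs, Xa, scales, scheme="forward", F0=Fa)
        # tiny ridge guards exactly singular Jacobians at degenerate points
        J = J + 1e-12 * eye
        try:
            delta = np.linalg.solve(J, -Fa[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.stack([
                np.linalg.lstsq(Ji, -fi, rcond=None)[0] for Ji, fi in zip(J, Fa)
            ])
        # cap steps at a multiple of the species scales to avoid overshoot
        cap = 10.0 * scales[None, :] + np.abs(Xa)
        delta = np.clip(delta, -cap, cap)
        fa = _merit(Fa, Xa, degradation, scales)
        best_X, best_f = Xa.copy(), fa.copy()
        improved = np.zeros(len(Xa), dtype=bool)
        alpha = 1.0
        for _bt in range(8):
            Xt = np.maximum(Xa + alpha * delta, 0.0)
            ft = _merit(rhs(Xt), Xt, degradation, scales)
            take = np.isfinite(ft) & (ft < best_f) & ~improved
            best_X[take] = Xt[take]
            best_f[take] = ft[take]
            improved |= take
            if np.all(improved):
                break
            alpha *= 0.5
        X[active] = best_X
        # rows that could not improve will never move again: settle them
        stalled = np.zeros(N, dtype=bool)
        stalled[np.flatnonzero(active)[~improved]] = True
        settled |= stalled
    F = rhs(X)
    fnorm = _merit(F, X, degradation, scales)
    converged = np.isfinite(fnorm) & (fnorm <= tol)
    return X, converged, fnorm


def integrate_to_steady(rhs, X0: np.ndarray, t_max: float, dt: float,
                        degradation: Optional[np.ndarray] = None,
                        scales: Optional[np.ndarray] = None,
                        tol: float = 1e-6, check_every: int = 50):
    """Fixed-step RK4 relaxation of a batch of states, clipped at 0.

    Returns ``(X, converged)`` where convergence means the per-species
    relative residual dropped below ``tol``.
    """
    X = np.array(np.atleast_2d(X0), dtype=float)
    if degradation is None:
        degradation = getattr(rhs, "degradation", np.ones(X.shape[1]))
    if scales is None:
        scales = getattr(rhs, "scales", np.ones(X.shape[1]))
    n_steps = int(np.ceil(t_max / dt))
    for step in range(n_steps):
        k1 = rhs(X)
        k2 = rhs(np.maximum(X + 0.5 * dt * k1, 0.0))
        k3 = rhs(np.maximum(X + 0.5 * dt * k2, 0.0))
        k4 = rhs(np.maximum(X + dt * k3, 0.0))
        X = np.maximum(X + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        bad = ~np.all(np.isfinite(X), axis=-1)
        if np.any(bad):
            X[bad] = 0.0  # diverged rows restart from the origin basin
        if step % check_every == check_every - 1:
            res = _merit(rhs(X), X, degradation, scales)
            if np.all(res < tol):
                break
    res = _merit(rhs(X), X, degradation, scales)
    return X, res < tol


def dedup_states(X: np.ndarray, scales: np.ndarray, tol: float = 1e-3) -> np.ndarray:
    """Merge near-identical rows; distance is max |log ratio| of shifted levels."""
    if len(X) == 0:
        return X
    shift = 1e-9 * scales[None, :] + 1e-30
    L = np.log(X + shift)
    order = np.lexsort(X.T[::-1])
    keep: list[int] = []
    kept_logs = np.empty((0, X.shape[1]))
    for i in order:
        if not len(keep) or np.min(np.max(np.abs(kept_logs - L[i]), axis=1)) > tol:
            keep.append(int(i))
            kept_logs = np.vstack([kept_logs, L[i]])
    return X[np.array(keep, dtype=int)]


def log_spaced_starts(scales: np.ndarray, n_starts: int, rng,
                      lo: float = 1e-4, hi: float = 30.0) -> np.ndarray:
    """Log-uniform multistart points spanning ``[lo, hi] * scale`` per species."""
    d = len(scales)
    u = rng.random((n_starts, d))
    return scales[None, :] * lo * (hi / lo) ** u


def find_steady_states(
    rhs,
    n_starts: int = 60,
    dedup_tol: float = 1e-3,
    stability_tol: float = 0.0,
    tol: float = 1e-9,
    scales: Optional[np.ndarray] = None,
    extra_starts: Optional[np.ndarray] = None,
    pre_integrate: bool = True,
    t_pre: float = 300.0,
    dt_pre: float = 0.25,
    seed: int = 0,
    zeb_index: Optional[int] = None,
    start_lo: float = 1e-4,
    start_hi: float = 30.0,
    newton_from_raw: bool = True,
    max_iter: int = 80,
) -> list[SteadyState]:
    """All distinct fixed points reachable from a multistart root search.

    Starts are log-spaced over the species scales (plus any ``extra_starts``,
    e.g. warm starts from a neighbouring SNAIL value); each is refined by
    damped Newton, optionally preceded by a short relaxation integration.
    Duplicates merge within ``dedup_tol`` (log-space); stability comes from
    the largest real part of the Jacobian eigenvalues.  Returns states sorted
    by their first coordinate (ties by the next coordinates).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if scales is None:
        scales = getattr(rhs, "scales")
    scales = np.asarray(scales, dtype=float)
    degradation = getattr(rhs, "degradation", np.ones(len(scales)))
    rng = np.random.default_rng(seed)
    starts = log_spaced_starts(scales, n_starts, rng, lo=start_lo, hi=start_hi)
    pools = [starts] if (newton_from_raw or not pre_integrate) else []
    if extra_starts is not None and len(extra_starts):
        pools.append(np.atleast_2d(np.asarray(extra_starts, dtype=float)))
    if pre_integrate:
        relaxed, _ = integrate_to_steady(rhs, starts, t_max=t_pre, dt=dt_pre,
                                         degradation=degradation, scales=scales)
        if not newton_from_raw:
            # relaxed starts cluster at the attractors; polishing one
            # representative per loose cluster is enough
            relaxed = dedup_states(relaxed, scales, tol=0.02)
        pools.append(relaxed)
    X0 = np.vstack(pools)
    X, converged, _res = newton_refine(rhs, X0, scales, degradation, tol=tol,
                                       max_iter=max_iter)
    X = X[converged & np.all(X >= 0, axis=-1) & np.all(np.isfinite(X), axis=-1)]
    if len(X) == 0:
        warnings.warn("no steady state found from any start", stacklevel=2)
        return []
    X = dedup_states(X, scales, tol=dedup_tol)
    X = X[np.lexsort(X.T[::-1])]

    out: list[SteadyState] = []
    J = batched_jacobian(rhs, X, scales)
    F = rhs(X)
    res = _merit(F, X, degradation, scales)
    for x, Ji, ri in zip(X, J, res):
        lead = float(np.max(np.linalg.eigvals(Ji).real))
        phen = classify_phenotype(x, zeb_index) if zeb_index is not None else None
        out.append(
            SteadyState(
                state=x,
                stable=bool(lead < -stability_tol),
                leading_eigenvalue=lead,
                residual=float(ri),
                phenotype=phen,
            )
        )
    return out
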