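"""Fixture circuits and the independence of solver vs brute-force oracle."""

import numpy as np
import pytest

from emtcircuits.fixtures import (
    brute_force_steady_states,
    enumerate_roots_1d,
    make_birth_death,
    make_self_activation,
    make_toggle,
    saddle_node_brackets,
    saddle_node_fold_condition,
    self_activation_rate,
)
from emtcircuits.model import build_rhs, species_scales
from emtcircuits.steady import batched_jacobian, find_steady_states


def _stable_oracle_clusters(fx, bounds, grid_density=25):
    """Brute-force clusters filtered to dynamically stable ones (symmetric
    initial conditions can ride a stable manifold into a saddle)."""
    rhs = build_rhs(fx.circuit, fx.params)
    scales = species_scales(fx.circuit, fx.params)
    res = brute_force_steady_states(rhs, bounds, grid_density=grid_density,
                                    scales=scales)
    keep = []
    for x in res.states:
        J = batched_jacobian(rhs, x[None, :], scales)
        if np.max(np.linalg.eigvals(J[0]).real) < 0:
            keep.append(x)
    return np.array(keep), res


FIXTURE_CASES = [
    (make_birth_death(), [(0.0, 600.0)]),
    (make_toggle(symmetric=True), [(0.0, 700.0), (0.0, 700.0)]),
    (make_toggle(symmetric=False), [(0.0, 800.0), (0.0, 800.0)]),
    (make_self_activation(), [(0.0, 1200.0)]),
]


@pytest.mark.parametrize("fx,bounds", FIXTURE_CASES,
                         ids=[f.name + ("_sym" if i != 2 else "_asym")
                              for i, (f, _) in enumerate(FIXTURE_CASES)])
def test_solver_matches_brute_force_oracle(fx, bounds):
    """Newton multistart reproduces the integration oracle's stable states
    to 1e-3 relative on every fixture."""
    rhs = build_rhs(fx.circuit, fx.params)
    states = find_steady_states(rhs, n_starts=80, seed=0)
    stable = np.array([s.state for s in states if s.stable])
    oracle, res = _stable_oracle_clusters(fx, bounds)
    assert res.n_nonconverged == 0
    assert len(stable) == len(oracle)
    order = np.lexsort(stable.T[::-1])
    order_o = np.lexsort(oracle.T[::-1])
    for a, b in zip(stable[order], oracle[order_o]):
        assert a == pytest.approx(b, rel=1e-3, abs=1e-6)


def test_birth_death_closed_form():
    fx = make_birth_death(g=20.0, k=0.1)
    assert fx.expected["stable_states"] == [[200.0]]
    rhs = build_rhs(fx.circuit, fx.params)
    res = brute_force_steady_states(rhs, [(0.0, 600.0)], grid_density=9)
    assert res.states.shape == (1, 1)
    assert res.states[0, 0] == pytest.approx(200.0, rel=1e-5)


def test_toggle_oracle_is_mirror_symmetric():
    fx = make_toggle(symmetric=True)
    oracle, _ = _stable_oracle_clusters(fx, [(0.0, 700.0), (0.0, 700.0)])
    assert len(oracle) == 2
    assert oracle[0] == pytest.approx(oracle[1][::-1], rel=1e-6)


def test_self_activation_roots_alternate_stability():
    """1-D index theory: between two stable roots of a scalar flow there is
    exactly one unstable root (sign changes alternate)."""
    fx = make_self_activation()
    rate = self_activation_rate(fx.params)
    roots = enumerate_roots_1d(rate, 1500.0)
    assert len(roots) == 3
    eps = 1e-3
    slopes = [np.sign(rate(r + eps) - rate(r - eps)) for r in roots]
    assert slopes == [-1.0, 1.0, -1.0]  # stable, unstable, stable


def test_self_activation_monostable_when_fold_is_one():
    fx = make_self_activation(fold=1.0)
    rate = self_activation_rate(fx.params)
    for g in (2.0, 10.0, 50.0):
        p = fx.params.copy()
        p["g_X"] = g
        roots = enumerate_roots_1d(self_activation_rate(p), 1e4)
        assert len(roots) == 1


def test_saddle_node_brackets_match_fold_condition():
    """Root-count bisection and the analytic fold condition agree to 1e-6
    relative on both saddle-node production rates."""
    fx = make_self_activation()
    g1, g2 = saddle_node_brackets(fx, rel_tol=1e-7)
    f1, f2 = saddle_node_fold_condition(fx)
    assert g1 == pytest.approx(f1, rel=1e-6)
    assert g2 == pytest.approx(f2, rel=1e-6)
    # inside the bracket the motif is bistable, outside monostable
    for g, n_expected in ((0.9 * g1, 1), (0.5 * (g1 + g2), 3), (1.1 * g2, 1)):
        p = fx.params.copy()
        p["g_X"] = g
        roots = enumerate_roots_1d(self_activation_rate(p), 5e3, n_grid=100_001)
        assert len(roots) == n_expected


def test_extended_circuit_cross_validates_both_solvers(extended_circuit,
                                                       extended_params):
    """At a monostable SNAIL level the integration oracle and the Newton
    multistart agree on the single attractor of the full extended circuit."""
    from emtcircuits.model import build_rhs as _build
    rhs = _build(extended_circuit, extended_params, snail=1.3e5)
    scales = species_scales(extended_circuit, extended_params)
    states = find_steady_states(rhs, n_starts=60, seed=2)
    stable = [s for s in states if s.stable]
    assert len(stable) == 1
    res = brute_force_steady_states(rhs, [(0.0, 10.0 * s) for s in scales],
                                    grid_density=2, scales=scales)
    assert len(res.states) == 1
    assert res.n_nonconverged == 0
    assert res.states[0] == pytest.approx(stable[0].state, rel=1e-3, abs=1e-6)


def test_neutral_circuit_relaxes_to_closed_form(simplified_circuit,
                                                simplified_params):
    """With every fold change at 1 and silencing disabled, levels relax to
    g/k (and g_Z/k_Z times the mRNA level for the translated protein) from
    any nonnegative start."""
    import numpy as np
    from emtcircuits.model import build_rhs as _build
    from emtcircuits.steady import integrate_to_steady
    p = simplified_params.copy()
    for k in list(p.values):
        if k.endswith("_lam"):
            p[k] = 1.0
        if "_l" in k and k.split("_l")[-1].isdigit():
            p[k] = 1.0
        if "_gm" in k and k.split("_gm")[-1].isdigit():
            p[k] = 0.0
        if "_gu" in k and k.split("_gu")[-1].isdigit():
            p[k] = 0.0
    rhs = _build(simplified_circuit, p, snail=2e5)
    mz = p["g_mZ"] / p["k_mZ"]
    expected = np.array([p["g_u200"] / p["k_u200"], mz, p["g_Z"] * mz / p["k_Z"]])
    rng = np.random.default_rng(0)
    x0 = rng.uniform(0.0, 3.0, size=(8, 3)) * expected
    x, conv = integrate_to_steady(rhs, x0, t_max=1500.0, dt=0.5, tol=1e-9)
    assert np.all(conv)
    assert x == pytest.approx(np.broadcast_to(expected, x.shape), rel=1e-5)


def test_brute_force_reports_trajectory_counts():
    fx = make_birth_death()
    rhs = build_rhs(fx.circuit, fx.params)
    res = brute_force_steady_states(rhs, [(0.0, 400.0)], grid_density=7)
    assert res.n_trajectories == 7
    assert res.n_nonconverged == 0
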