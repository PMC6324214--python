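"""Assemble the ODE right-hand side of a parameterized regulatory circuit.

For each dynamical species ``X`` the rate is

    dX/dt = production(X) * prod_of_shifted_Hill_factors * L(mu)  -  k_X * X
            - X * Ym(mu)                    (microRNA-silenced mRNA targets)

with the microRNA itself losing ``target * Ymu(mu)`` per silenced target.
Production is ``g_X`` for transcribed/synthesized species, ``g_X * mRNA`` for
proteins translated from a template mRNA, and a splicing-partition share of
the total ``g_C`` for CD44 isoforms.  The external control parameter (SNAIL)
enters only through its outgoing regulatory edges, at the fixed level passed
to :func:`build_rhs`.

The returned callable is deterministic, side-effect free, and vectorized:
it maps state arrays of shape ``(..., n_species)`` to derivatives of the same
shape, which lets the steady-state solver run many multistarts in one batch.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .circuit import RegulatoryCircuit
from .kinetics import (
    ConfigurationError,
    KineticParameterSet,
    _bound_fraction,
    _hill_factor,
    _splicing_core,
)

REGULATORY_MODES = ("transcriptional", "nontranscriptional")


def validate_params(circuit: RegulatoryCircuit, params: KineticParameterSet) -> None:
    """Check that every edge/species has exactly one parameter block.

    Raises :class:`ConfigurationError` naming the offending edge or species.
    """
    required: set[str] = set()
    for sp in circuit.species:
        spliced = any(e.mode == "splicing" for e in circuit.edges_into(sp.name))
        if spliced or (f"g_{sp.name}" not in params and "g_C" in params):
            # CD44 splice isoforms draw from the shared total g_C (a species
            # whose splicing edge was knocked out keeps a constitutive share)
            required.add("g_C")
        else:
            required.add(f"g_{sp.name}")
        required.add(f"k_{sp.name}")
    has_splicing = False
    for e in circuit.edges:
        if e.mode in REGULATORY_MODES:
            for suffix in ("X0", "n", "lam"):
                required.add(f"h_{e.source}_{e.target}_{suffix}")
        elif e.mode == "microRNA_translational":
            base = f"mir_{e.source}_{e.target}"
            required.add(f"{base}_mu0")
            required.add(f"{base}_sites")
            if f"{base}_sites" in params:
                n = int(round(params[f"{base}_sites"]))
                for i in range(1, n + 1):
                    required.update({f"{base}_l{i}", f"{base}_gm{i}", f"{base}_gu{i}"})
        elif e.mode == "splicing":
            has_splicing = True
    if has_splicing:
        required.update({"g_C", "spl_X0", "spl_n"})

    missing = sorted(required - set(params.values))
    if missing:
        raise ConfigurationError(
            f"circuit {circuit.name!r}: missing parameters {missing}"
        )
    orphan = sorted(set(params.values) - required)
    if orphan:
        raise ConfigurationError(
            f"circuit {circuit.name!r}: orphan parameters {orphan}"
        )


def _production_rate(circuit: RegulatoryCircuit, params: KineticParameterSet, name: str) -> float:
    """Base production of one species: own ``g``, or a half share of ``g_C``
    for CD44 splice isoforms (species without their own ``g`` entry)."""
    if f"g_{name}" in params:
        return params[f"g_{name}"]
    if "g_C" in params:
        return 0.5 * params["g_C"]
    raise ConfigurationError(f"species {name!r}: no production parameter g_{name} (and no g_C)")


def species_scales(circuit: RegulatoryCircuit, params: KineticParameterSet) -> np.ndarray:
    """Characteristic level ``~ g/k`` per species (used to seed multistarts)."""
    scales = np.empty(len(circuit.species))
    base = {
        sp.name: _production_rate(circuit, params, sp.name) / params[f"k_{sp.name}"]
        for sp in circuit.species
    }
    for i, sp in enumerate(circuit.species):
        scale = base[sp.name]
        if sp.template is not None:
            scale *= base[sp.template]
        scales[i] = scale
    return scales


def build_rhs(
    circuit: RegulatoryCircuit,
    params: KineticParameterSet,
    snail: float = 0.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Compile the vectorized derivative function for one (circuit, params, SNAIL).

    ``snail`` is the fixed level of the external control parameter; it is
    ignored for circuits without control-parameter edges.
    """
    validate_params(circuit, params)
    if snail < 0:
        raise ValueError("control-parameter level must be >= 0")
    names = circuit.species_names
    idx = {n: i for i, n in enumerate(names)}
    control = circuit.control_parameter
    d = len(names)

    # per-species compiled term lists ---------------------------------------
    # hill_terms[i]: list of (source_index or None(=SNAIL), cofactor_index or None, X0, n, lam)
    hill_terms: list[list[tuple]] = [[] for _ in range(d)]
    # translation: (template_index,) per protein with template, else None
    template_idx = [None] * d
    # silencing acting on mRNA i: list of (mirna_index, mu0, n_sites, gm_vec, gu_vec, l_vec)
    silencing_on: list[list[tuple]] = [[] for _ in range(d)]
    # splicing share per species: None | ('s'|'v', E1_index, g_C, X0, n)
    splice_share = [None] * d

    for e in circuit.edges:
        t = idx[e.target]
        if e.mode in REGULATORY_MODES:
            reg = params.hill(e.source, e.target)
            # lam = 1 is a neutral (disabled) regulation, allowed either way
            if (e.sign == "activation" and reg.fold_change < 1.0) or (
                    e.sign == "inhibition" and reg.fold_change > 1.0):
                raise ConfigurationError(
                    f"edge {e.source}->{e.target}: sign {e.sign!r} inconsistent "
                    f"with fold change {reg.fold_change}"
                )
            s = None if e.source == control else idx[e.source]
            c = None if e.cofactor is None else idx[e.cofactor]
            hill_terms[t].append((s, c, reg.threshold, reg.coefficient, reg.fold_change))
        elif e.mode == "microRNA_translational":
            sil = params.silencing(e.source, e.target)
            i_arr = np.arange(sil.n_sites + 1, dtype=float)
            silencing_on[t].append(
                (
                    idx[e.source],
                    sil.mu0,
                    sil.n_sites,
                    np.asarray(sil.gamma_m),
                    i_arr * np.asarray(sil.gamma_mu),
                    np.asarray(sil.l),
                )
            )
        elif e.mode == "splicing":
            which = "v" if e.sign == "activation" else "s"
            splice_share[t] = (which, idx[e.source], params["g_C"], params["spl_X0"], params["spl_n"])

    g = np.zeros(d)
    k = np.empty(d)
    for i, sp in enumerate(circuit.species):
        k[i] = params[f"k_{sp.name}"]
        if splice_share[i] is None:
            # isoforms whose splicing edge was knocked out keep a constitutive
            # half share of g_C (the neutralized partition)
            g[i] = _production_rate(circuit, params, sp.name)
        if sp.template is not None:
            template_idx[i] = idx[sp.template]

    def rhs(state: np.ndarray) -> np.ndarray:
        x = np.maximum(np.asarray(state, dtype=float), 0.0)
        out = np.empty_like(x)
        # silencing factors, computed once per silenced mRNA
        sil_cache = {}
        for t in range(d):
            for (m, mu0, n_sites, gm, igu, l_vec) in silencing_on[t]:
                M = _bound_fraction(x[..., m], mu0, n_sites)
                sil_cache[(m, t)] = (M @ l_vec, M @ gm, M @ igu)

        for i in range(d):
            if splice_share[i] is not None:
                which, e1, gc, X0, n = splice_share[i]
                f = _splicing_core(x[..., e1], X0, n)
                prod = gc * (f if which == "v" else 1.0 - f)
            else:
                prod = g[i]  # scalar; broadcasts through the factor products
            for (s, c, X0, n, lam) in hill_terms[i]:
                reg = snail if s is None else x[..., s]
                if c is not None:
                    reg = reg * x[..., c]
                prod = prod * _hill_factor(reg, X0, n, lam)
            ti = template_idx[i]
            if ti is not None:
                prod = prod * x[..., ti]
                for key, (L, _, _) in sil_cache.items():
                    if key[1] == ti:
                        prod = prod * L
            rate = prod - k[i] * x[..., i]
            # losses on the silenced mRNA itself
            for key, (_, Ym, _) in sil_cache.items():
                if key[1] == i:
                    rate = rate - x[..., i] * Ym
            # microRNA turnover on each of its silenced targets
            for (m, t), (_, _, Ymu) in sil_cache.items():
                if m == i:
                    rate = rate - x[..., t] * Ymu
            out[..., i] = rate
        return out

    rhs.circuit = circuit  # type: ignore[attr-defined]
    rhs.n_species = d  # type: ignore[attr-defined]
    rhs.degradation = k  # type: ignore[attr-defined]
    rhs.scales = species_scales(circuit, params)  # type: ignore[attr-defined]
    rhs.snail = snail  # type: ignore[attr-defined]
    return rhs
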