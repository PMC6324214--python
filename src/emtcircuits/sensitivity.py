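"""One-at-a-time ±10% parameter sensitivity of the hybrid-region width.

Every kinetic parameter is multiplied, one at a time, by 1 ± ``perturbation``;
the bifurcation diagram is recomputed and the change in the SNAIL width of
the hybrid-supporting region is reported as a signed percent of the baseline.
Parameters whose absolute change exceeds the ±20% guide line are *flagged*.

MicroRNA-silencing coefficient vectors are perturbed as blocks (one common
scale factor on the free entries), which preserves their shape constraints
(``l0 = 1``, ``gamma0 = 0``); binding-site counts are structural and not
scanned.  Perturbed diagrams are warm-started from the baseline branches at
every grid point (the ±10% shifts are small), which keeps the full scan cheap
without changing the baseline sweep itself.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bifurcation import BifurcationDiagram, hybrid_region_width, sweep_bifurcation
from .circuit import RegulatoryCircuit
from .kinetics import ConfigurationError, KineticParameterSet

_BLOCK_RE = re.compile(r"^(mir_\w+?)_(l|gm|gu)_block$")
_VECTOR_ENTRY_RE = re.compile(r"^(mir_\w+?)_(l|gm|gu)(\d+)$")


@dataclass
class SensitivityRecord:
    """Hybrid-width response to one parameter moved in one direction."""

    parameter: str
    group: str
    direction: str            # '+10%' / '-10%'
    baseline_width: float     # SNAIL units (molecules)
    perturbed_width: float
    percent_change: float     # 100 * (perturbed - baseline) / baseline
    flagged: bool             # |percent_change| > flag threshold


def parameter_group(name: str) -> str:
    """Functional group of a parameter (the Fig-2(b)-style grouping)."""
    if name.startswith(("g_",)):
        return "production"
    if name.startswith("k_"):
        return "degradation"
    if name.endswith("_X0") and name.startswith("h_"):
        return "hill_threshold"
    if name.endswith("_n") and name.startswith("h_"):
        return "hill_coefficient"
    if name.endswith("_lam"):
        return "fold_change"
    if name.startswith("spl_"):
        return "splicing"
    if name.startswith("mir_"):
        return "silencing"
    return "other"


def perturbable_parameters(params: KineticParameterSet) -> list[tuple[str, str]]:
    """(name, group) of every scannable parameter.

    Scalar entries appear individually; each silencing vector appears once as
    a ``..._{l,gm,gu}_block`` pseudo-parameter; ``mir_*_sites`` is structural
    and excluded.
    """
    out: list[tuple[str, str]] = []
    blocks: list[str] = []
    for name in params:
        if name.endswith("_sites"):
            continue
        m = _VECTOR_ENTRY_RE.match(name)
        if m:
            block = f"{m.group(1)}_{m.group(2)}_block"
            if block not in blocks:
                blocks.append(block)
            continue
        out.append((name, parameter_group(name)))
    out.extend((b, "silencing") for b in blocks)
    return out


def perturb(params: KineticParameterSet, name: str, factor: float) -> KineticParameterSet:
    """Copy of ``params`` with one parameter (or one silencing block) scaled.

    Everything else is bit-identical; unknown names raise
    :class:`ConfigurationError`.
    """
    if factor <= 0:
        raise ValueError("perturbation factor must be > 0")
    new = params.copy()
    m = _BLOCK_RE.match(name)
    if m:
        prefix = f"{m.group(1)}_{m.group(2)}"
        entries = [k for k in params if _VECTOR_ENTRY_RE.match(k)
                   and k.startswith(prefix) and k[len(prefix):].isdigit()]
        if not entries:
            raise ConfigurationError(f"unknown silencing block {name!r}")
        for k in entries:
            new[k] = params[k] * factor
        return new
    if name not in params:
        raise ConfigurationError(f"unknown parameter {name!r}")
    new[name] = params[name] * factor
    return new


def sensitivity_scan(
    circuit: RegulatoryCircuit,
    params: KineticParameterSet,
    snail_grid: Sequence[float],
    perturbation: float = 0.10,
    flag_threshold: float = 0.20,
    subset: Optional[Sequence[str]] = None,
    baseline: Optional[BifurcationDiagram] = None,
    seed: int = 0,
    fresh_starts: int = 0,
) -> pd.DataFrame:
    """±``perturbation`` one-at-a-time scan of the hybrid-region width.

    Returns a table with two :class:`SensitivityRecord` rows per parameter
    (grouped by the parameter's circuit role).  ``subset`` restricts the scan
    to the named parameters (smoke mode).  The baseline width is computed by
    the same bifurcation sweep the records are measured against, so a
    zero-perturbation control run reports exactly 0% change.
    """
    snail_grid = np.asarray(snail_grid, dtype=float)
    if baseline is None:
        baseline = sweep_bifurcation(circuit, params, snail_grid, seed=seed)
    w0 = hybrid_region_width(baseline)
    if w0 <= 0:
        raise ValueError("baseline diagram has no hybrid region to perturb")
    warm = [
        np.array([s.state for s in roots]) if roots else None
        for roots in baseline.states
    ]

    names = perturbable_parameters(params)
    if subset is not None:
        wanted = set(subset)
        names = [(n, g) for n, g in names if n in wanted]
        missing = wanted - {n for n, _ in names}
        if missing:
            raise ConfigurationError(f"unknown parameters in subset: {sorted(missing)}")

    rows = []
    for name, group in names:
        for factor, direction in ((1.0 + perturbation, f"+{perturbation:.0%}"),
                                  (1.0 - perturbation, f"-{perturbation:.0%}")):
            p = perturb(params, name, factor)
            diagram = sweep_bifurcation(
                circuit, p, snail_grid, n_starts=fresh_starts,
                warm_states=warm, seed=seed,
            )
            if all(not roots for roots in diagram.states):
                warnings.warn(f"perturbed model {name} {direction} lost all "
                              "steady states; recording width 0", stacklevel=2)
                w = 0.0
            else:
                w = hybrid_region_width(diagram)
            pct = 100.0 * (w - w0) / w0
            rows.append(SensitivityRecord(
                parameter=name, group=group, direction=direction,
                baseline_width=w0, perturbed_width=w, percent_change=pct,
                flagged=bool(abs(pct) > 100.0 * flag_threshold),
            ))
    frame = pd.DataFrame([r.__dict__ for r in rows])
    order = ["production", "degradation", "hill_threshold", "hill_coefficient",
             "fold_change", "splicing", "silencing", "other"]
    frame["group"] = pd.Categorical(frame["group"], categories=order, ordered=True)
    return frame.sort_values(["group", "parameter", "direction"]).reset_index(drop=True)
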