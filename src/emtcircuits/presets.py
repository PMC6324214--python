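"""Packaged circuit topologies and default kinetic parameter sets.

Three topologies ship with the package:

* ``simplified`` — the miR-200/ZEB1 mutual-inhibition loop driven by SNAIL,
  with direct ZEB1 transcriptional self-activation;
* ``extended`` — the miR-200/ZEB1/ESRP1/HAS2/CD44 circuit in which the
  self-activation is resolved mechanistically (ZEB1 ⊣ ESRP1, ESRP1-controlled
  CD44s/CD44v splicing, CD44s → ZEB1, CD44v ⊣ ZEB1, ZEB1 → HAS2 → HA with HA
  acting on ZEB1 only in complex with CD44s);
* ``cd44`` — the miR-200/ZEB/ESRP1/CD44 reduction (no HAS2/HA, no SNAIL input)
  used for the random-parameter ensemble analysis.

The miR-200/ZEB1 core parameters are the published molecule-count/hour
baseline of this model family; the extended circuit's new edges were
calibrated once so that the five-phase SNAIL response and the ZEB1-mRNA
branch ranges (E < 150, hybrid ~ 200-500, M > 600 molecules) hold (see
docs/methods.md).  Species names: ``u200`` miR-200, ``mZ`` ZEB1 mRNA, ``Z``
ZEB1 protein, ``E1`` ESRP1, ``H2`` HAS2, ``HA`` hyaluronic acid, ``Cs``/``Cv``
the CD44 splice isoforms; ``S`` is the SNAIL control parameter.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .circuit import RegulatoryCircuit, read_topology
from .kinetics import KineticParameterSet

#: ZEB1-mRNA species name (the bifurcation readout)
ZEB_MRNA = "mZ"

#: default SNAIL scan grid (molecules): all five phases of both shipped
#: circuits are interior to this range at 400 points
SNAIL_RANGE = (120_000.0, 260_000.0)
SNAIL_POINTS = 400

_TOPOLOGIES = ("simplified", "extended", "cd44")


def _data_path(filename: str):
    return resources.files("emtcircuits.data").joinpath(filename)


def load_circuit(name: str) -> RegulatoryCircuit:
    """Load a packaged topology: ``simplified``, ``extended`` or ``cd44``."""
    if name not in _TOPOLOGIES:
        raise KeyError(f"unknown circuit {name!r}; choose from {_TOPOLOGIES}")
    with resources.as_file(_data_path(f"{name}.topo")) as p:
        return read_topology(p)


def load_params(name: str) -> KineticParameterSet:
    """Load a packaged default parameter set, e.g. ``extended_default``."""
    with resources.as_file(_data_path(f"{name}.params")) as p:
        return KineticParameterSet.from_file(p)


def default_snail_grid(n: int = SNAIL_POINTS) -> np.ndarray:
    return np.linspace(*SNAIL_RANGE, n)
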