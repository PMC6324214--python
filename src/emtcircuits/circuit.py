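"""Regulatory-circuit data model and topology file I/O.

A :class:`RegulatoryCircuit` is a list of molecular species plus a list of
signed, typed regulatory edges, together with the name of the external control
parameter (SNAIL in the epithelial-mesenchymal circuits shipped with this
package).  Circuits are stored on disk in a small whitespace-separated dialect
(``.topo``)::

    # comment
    node  <name> <kind> [<template mRNA>]   # kind in {mRNA, protein, microRNA, metabolite}
    control <name>                          # external control parameter (not a species)
    <source> <target> <sign> <mode> [@<cofactor>]

with ``sign`` in ``{activation, inhibition}`` and ``mode`` in
``{transcriptional, microRNA_translational, splicing, nontranscriptional}``.
A protein node may name the mRNA it is translated from (translation coupling);
an edge may name a cofactor species (``@Cs``): the regulatory input of such an
edge is the product of the source and cofactor levels, so the regulation
vanishes whenever the cofactor is absent (used for the CD44s-gated action of
hyaluronic acid on ZEB1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

SPECIES_KINDS = ("mRNA", "protein", "microRNA", "metabolite")
EDGE_SIGNS = ("activation", "inhibition")
EDGE_MODES = (
    "transcriptional",
    "microRNA_translational",
    "splicing",
    "nontranscriptional",
)


class TopologyError(ValueError):
    """Malformed topology file or inconsistent circuit structure."""


@dataclass(frozen=True)
class Species:
    """One molecular species (node) of a circuit.

    ``template`` names the mRNA a protein is translated from; production of
    such a protein is proportional to the template level.
    """

    name: str
    kind: str = "protein"
    initial_level: float = 0.0
    template: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in SPECIES_KINDS:
            raise TopologyError(f"unknown species kind {self.kind!r} for {self.name!r}")
        if self.initial_level < 0:
            raise TopologyError(f"initial_level of {self.name!r} must be >= 0")
        if self.template is not None and self.kind != "protein":
            raise TopologyError(f"only proteins may declare a template mRNA ({self.name!r})")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed, typed regulation source -> target."""

    source: str
    target: str
    sign: str
    mode: str = "transcriptional"
    cofactor: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sign not in EDGE_SIGNS:
            raise TopologyError(f"unknown edge sign {self.sign!r}")
        if self.mode not in EDGE_MODES:
            raise TopologyError(f"unknown edge mode {self.mode!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass
class RegulatoryCircuit:
    """Species, edges, and the external control parameter of one circuit."""

    species: list[Species] = field(default_factory=list)
    edges: list[RegulatoryEdge] = field(default_factory=list)
    control_parameter: Optional[str] = None
    name: str = "circuit"

    def __post_init__(self) -> None:
        self.validate()

    # -- structure queries -------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def has_species(self, name: str) -> bool:
        return name in self.species_names

    def edges_into(self, target: str, modes: Optional[Iterable[str]] = None) -> list[RegulatoryEdge]:
        out = [e for e in self.edges if e.target == target]
        if modes is not None:
            modes = tuple(modes)
            out = [e for e in out if e.mode in modes]
        return out

    def find_edge(self, source: str, target: str) -> RegulatoryEdge:
        for e in self.edges:
            if e.key == (source, target):
                return e
        raise KeyError(f"no edge {source}->{target}")

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        names = self.species_names
        if len(set(names)) != len(names):
            raise TopologyError("duplicate species names")
        valid_sources = set(names)
        if self.control_parameter is not None:
            if self.control_parameter in names:
                raise TopologyError("control parameter must not also be a species")
            valid_sources.add(self.control_parameter)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in valid_sources:
                raise TopologyError(f"edge source {e.source!r} is not declared")
            if e.target not in names:
                raise TopologyError(f"edge target {e.target!r} is not declared")
            if e.cofactor is not None and e.cofactor not in names:
                raise TopologyError(f"edge cofactor {e.cofactor!r} is not declared")
            if e.key in seen:
                raise TopologyError(f"duplicate edge {e.source}->{e.target}")
            seen.add(e.key)
            if e.mode == "microRNA_translational":
                if e.source == self.control_parameter:
                    raise TopologyError("control parameter cannot act as a microRNA")
                if self.get_species(e.source).kind != "microRNA":
                    raise TopologyError(
                        f"microRNA_translational edge {e.source}->{e.target} "
                        "requires a microRNA source"
                    )
        for s in self.species:
            if s.template is not None and s.template not in names:
                raise TopologyError(f"template mRNA {s.template!r} of {s.name!r} is not declared")

    # -- editing -----------------------------------------------------------

    def without_edge(self, source: str, target: str, name_suffix: str = "") -> "RegulatoryCircuit":
        """Return a copy of the circuit with one edge removed."""
        edge = self.find_edge(source, target)  # KeyError if absent
        edges = [e for e in self.edges if e is not edge]
        return RegulatoryCircuit(
            species=list(self.species),
            edges=edges,
            control_parameter=self.control_parameter,
            name=self.name + (name_suffix or f"_ko_{source}_{target}"),
        )


# ---------------------------------------------------------------------------
# topology file I/O
# ---------------------------------------------------------------------------

def read_topology(path) -> RegulatoryCircuit:
    """Parse a ``.topo`` file; raises :class:`TopologyError` with line numbers."""
    path = Path(path)
    species: list[Species] = []
    edges: list[RegulatoryEdge] = []
    control: Optional[str] = None
    declared: set[str] = set()

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        try:
            if tokens[0] == "node":
                if len(tokens) not in (3, 4):
                    raise TopologyError("node line needs: node NAME KIND [TEMPLATE]")
                template = tokens[3] if len(tokens) == 4 else None
                sp = Species(name=tokens[1], kind=tokens[2], template=template)
                if sp.name in declared:
                    raise TopologyError(f"duplicate node {sp.name!r}")
                species.append(sp)
                declared.add(sp.name)
            elif tokens[0] == "control":
                if len(tokens) != 2:
                    raise TopologyError("control line needs: control NAME")
                control = tokens[1]
            else:
                cofactor = None
                if tokens and tokens[-1].startswith("@"):
                    cofactor = tokens[-1][1:]
                    tokens = tokens[:-1]
                if len(tokens) != 4:
                    raise TopologyError(
                        "edge line needs: SOURCE TARGET SIGN MODE [@COFACTOR]"
                    )
                src, tgt, sign, mode = tokens
                if src not in declared and src != control:
                    raise TopologyError(f"edge references undeclared node {src!r}")
                if tgt not in declared:
                    raise TopologyError(f"edge references undeclared node {tgt!r}")
                edges.append(RegulatoryEdge(src, tgt, sign, mode, cofactor=cofactor))
        except TopologyError as err:
            raise TopologyError(f"{path.name}:{lineno}: {err}") from None

    circuit = RegulatoryCircuit(
        species=species, edges=edges, control_parameter=control, name=path.stem
    )
    return circuit


def write_topology(circuit: RegulatoryCircuit, path) -> None:
    """Write a circuit in the ``.topo`` dialect (round-trips exactly)."""
    lines = [f"# circuit: {circuit.name}"]
    for s in circuit.species:
        entry = f"node {s.name} {s.kind}"
        if s.template is not None:
            entry += f" {s.template}"
        lines.append(entry)
    if circuit.control_parameter is not None:
        lines.append(f"control {circuit.control_parameter}")
    for e in circuit.edges:
        entry = f"{e.source} {e.target} {e.sign} {e.mode}"
        if e.cofactor is not None:
            entry += f" @{e.cofactor}"
        lines.append(entry)
    Path(path).write_text("\n".join(lines) + "\n")
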