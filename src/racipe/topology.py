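"""Gene circuit topologies: the sole biological input of the method.

A circuit is a directed signed graph: genes (nodes) and regulatory edges,
each either an ACTIVATION or an INHIBITION.  Topologies are read from and
written to a plain tab-delimited ``Source<TAB>Target<TAB>Type`` file with
Type 1 = activation, 2 = inhibition (word tokens are accepted too); an
optional header row starting with "Source" and comment lines starting with
``#`` are skipped.  Gene order is first-appearance order and fixes the
column order of every downstream table.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

__all__ = [
    "Sign",
    "Gene",
    "RegulatoryEdge",
    "CircuitTopology",
    "TopologyError",
    "TopologyParseError",
    "DuplicateEdgeError",
    "parse_topology",
    "parse_topology_lines",
    "write_topology",
    "builtin_circuit",
    "BUILTIN_CIRCUITS",
]


class TopologyError(ValueError):
    """Invalid circuit topology."""


class TopologyParseError(TopologyError):
    """Malformed topology file; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateEdgeError(TopologyError):
    """More than one edge for the same ordered (source, target) pair."""


class Sign(enum.Enum):
    ACTIVATION = 1
    INHIBITION = 2

    @classmethod
    def from_token(cls, token: str) -> "Sign":
        token = token.strip().lower()
        if token in ("1", "activation"):
            return cls.ACTIVATION
        if token in ("2", "inhibition"):
            return cls.INHIBITION
        raise ValueError(f"unknown interaction type {token!r} (expected 1, 2, "
                         f"'activation' or 'inhibition')")


@dataclass(frozen=True)
class Gene:
    """A circuit node.  ``role_tag`` (e.g. "TF", "miR") is metadata only."""

    name: str
    role_tag: Optional[str] = None

    def __post_init__(self):
        if not self.name:
            raise TopologyError("gene name must be a non-empty string")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed, directed regulatory link (source regulates target)."""

    source: str
    target: str
    sign: Sign


class CircuitTopology:
    """An ordered gene list plus signed regulatory edges.

    Gene order is deterministic (construction / file order) and defines the
    column order of all expression and parameter tables.  At most one edge
    per ordered (source, target) pair; self-edges are allowed.
    """

    def __init__(self, genes: Iterable[Union[Gene, str]],
                 edges: Iterable[RegulatoryEdge] = (),
                 name: Optional[str] = None):
        self.name = name
        self.genes: list[Gene] = [
            g if isinstance(g, Gene) else Gene(g) for g in genes
        ]
        if not self.genes:
            raise TopologyError("a topology must contain at least one gene")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TopologyError(f"duplicate gene names: {dupes}")
        self._index = {g.name: i for i, g in enumerate(self.genes)}
        self.edges: list[RegulatoryEdge] = []
        for e in edges:
            self.add_edge(e)

    # -- construction -----------------------------------------------------
    def add_edge(self, edge: RegulatoryEdge) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self._index:
                raise TopologyError(
                    f"edge endpoint {endpoint!r} is not a gene of this topology")
        if any(e.source == edge.source and e.target == edge.target
               for e in self.edges):
            raise DuplicateEdgeError(
                f"duplicate edge {edge.source} -> {edge.target}")
        self.edges.append(edge)

    # -- basic queries ----------------------------------------------------
    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def gene_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise TopologyError(f"unknown gene {name!r}") from None

    def edges_into(self, gene: str) -> list[tuple[int, RegulatoryEdge]]:
        """Inward edges of ``gene`` as (edge_index, edge), in file order."""
        return [(i, e) for i, e in enumerate(self.edges) if e.target == gene]

    def edges_out_of(self, gene: str) -> list[tuple[int, RegulatoryEdge]]:
        return [(i, e) for i, e in enumerate(self.edges) if e.source == gene]

    def activators_of(self, gene: str) -> list[tuple[int, RegulatoryEdge]]:
        return [(i, e) for i, e in self.edges_into(gene)
                if e.sign is Sign.ACTIVATION]

    # -- dunder -----------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, CircuitTopology):
            return NotImplemented
        return (self.gene_names == other.gene_names
                and set((e.source, e.target, e.sign) for e in self.edges)
                == set((e.source, e.target, e.sign) for e in other.edges))

    def __repr__(self) -> str:
        label = f" {self.name!r}" if self.name else ""
        return (f"<CircuitTopology{label}: {self.n_genes} genes, "
                f"{self.n_edges} edges>")

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def parse_topology_lines(lines: Iterable[str],
                         name: Optional[str] = None) -> CircuitTopology:
    """Parse topology rows (``Source Target Type``) from an iterable of lines."""
    gene_order: list[str] = []
    seen: set[str] = set()
    rows: list[tuple[str, str, Sign, int]] = []
    first_data_line = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if first_data_line:
            first_data_line = False
            if fields[0].lower() == "source":
                continue
        if len(fields) < 3:
            raise TopologyParseError(
                f"expected at least 3 fields (source, target, type), "
                f"got {len(fields)}: {line!r}", line=lineno)
        src, tgt, token = fields[0], fields[1], fields[2]
        try:
            sign = Sign.from_token(token)
        except ValueError as exc:
            raise TopologyParseError(str(exc), line=lineno) from None
        for g in (src, tgt):
            if g not in seen:
                seen.add(g)
                gene_order.append(g)
        rows.append((src, tgt, sign, lineno))

    if not gene_order:
        raise TopologyParseError("no circuit rows found (empty topology)")
    topo = CircuitTopology(gene_order, name=name)
    for src, tgt, sign, lineno in rows:
        try:
            topo.add_edge(RegulatoryEdge(src, tgt, sign))
        except DuplicateEdgeError as exc:
            raise DuplicateEdgeError(f"line {lineno}: {exc}") from None
    return topo


def parse_topology(path: Union[str, Path]) -> CircuitTopology:
    """Read a tab/whitespace-delimited topology file."""
    path = Path(path)
    with open(path) as fh:
        return parse_topology_lines(fh, name=path.stem)


def write_topology(topology: CircuitTopology, path: Union[str, Path]) -> None:
    """Write ``Source<TAB>Target<TAB>Type`` rows (Type 1/2) with a header.

    Round-trip guarantee: ``parse_topology`` of the written file compares
    equal to ``topology``.
    """
    with open(path, "w") as fh:
        fh.write("Source\tTarget\tType\n")
        for e in topology.edges:
            fh.write(f"{e.source}\t{e.target}\t{e.sign.value}\n")


# ---------------------------------------------------------------------------
# built-in circuits
# ---------------------------------------------------------------------------

def _ts(name="TS", self_act: Sequence[str] = ()) -> CircuitTopology:
    topo = CircuitTopology(["A", "B"], name=name)
    topo.add_edge(RegulatoryEdge("A", "B", Sign.INHIBITION))
    topo.add_edge(RegulatoryEdge("B", "A", Sign.INHIBITION))
    for g in self_act:
        topo.add_edge(RegulatoryEdge(g, g, Sign.ACTIVATION))
    return topo


def _coupled_toggle_switches(k: int) -> CircuitTopology:
    """Chain of ``k`` toggle switches (genes A1,B1..Ak,Bk).

    Within switch i, Ai and Bi mutually inhibit.  Consecutive switches are
    coupled directionally: Ai activates Ai+1 and Bi+1 activates Bi (one
    activation each way per junction, 2(k-1) coupling edges in total, so
    2k + 2(k-1) edges overall).

    The direction matters.  With this coupling a domain wall of the form
    "A-high switches on the right, B-high switches on the left" is
    unfrustrated (neither neighbour pushes against the other), while the
    mirrored wall is doubly frustrated; hence exactly one wall orientation
    is favoured and the circuit supports the two aligned extremes plus one
    intermediate state per junction — k+1 gene states in which consecutive
    switches flip one at a time.  Symmetric (bidirectional) coupling was
    also examined and yields walls of both orientations, i.e. more than
    k+1 states, contrary to the cascade this fixture is meant to embody.
    """
    if k < 2:
        raise TopologyError("coupled toggle switch chain needs k >= 2")
    if k > 5:
        warnings.warn(f"CTS with k={k} switches is outside the usual 2..5 "
                      "range", stacklevel=3)
    genes = [f"{x}{i}" for i in range(1, k + 1) for x in "AB"]
    topo = CircuitTopology(genes, name=f"CTS{k}")
    for i in range(1, k + 1):
        topo.add_edge(RegulatoryEdge(f"A{i}", f"B{i}", Sign.INHIBITION))
        topo.add_edge(RegulatoryEdge(f"B{i}", f"A{i}", Sign.INHIBITION))
    for i in range(1, k):
        topo.add_edge(RegulatoryEdge(f"A{i}", f"A{i+1}", Sign.ACTIVATION))
        topo.add_edge(RegulatoryEdge(f"B{i+1}", f"B{i}", Sign.ACTIVATION))
    return topo


def _repressilator() -> CircuitTopology:
    topo = CircuitTopology(["A", "B", "C"], name="REPRESSILATOR")
    topo.add_edge(RegulatoryEdge("A", "B", Sign.INHIBITION))
    topo.add_edge(RegulatoryEdge("B", "C", Sign.INHIBITION))
    topo.add_edge(RegulatoryEdge("C", "A", Sign.INHIBITION))
    return topo


def _emt22() -> CircuitTopology:
    """22-node EMT decision circuit (13 TFs incl. the CDH1/VIM readouts,
    9 microRNAs, 82 regulatory links).

    The edge list is a synthetic reconstruction from canonical EMT
    regulatory interactions (see the ``emt22_synthetic.topo`` data file,
    which documents every edge); the original curated list was not
    redistributable.  Structural constraints honoured: miR-30c, miR-205 and
    miR-9 receive no regulation (pure inputs), microRNAs and CDH1 form one
    co-expressed block opposing the TF/VIM block, and the miR-200/ZEB and
    miR-34/SNAIL mutual-inhibition loops form the decision cascade.
    """
    ref = resources.files("racipe.data").joinpath("emt22_synthetic.topo")
    with ref.open() as fh:
        topo = parse_topology_lines(fh, name="EMT22")
    mirs = {g.name for g in topo.genes if g.name.startswith("miR")}
    topo.genes = [Gene(g.name, "miR" if g.name in mirs else "TF")
                  for g in topo.genes]
    return topo


BUILTIN_CIRCUITS = ("TS", "TS1SA", "TS2SA", "CTS", "REPRESSILATOR", "EMT22")


def builtin_circuit(name: str, k: Optional[int] = None) -> CircuitTopology:
    """Return one of the built-in fixture circuits.

    Parameters
    ----------
    name : one of TS, TS1SA, TS2SA, CTS, REPRESSILATOR, EMT22
        TS is the two-gene mutual-inhibition toggle switch; TS1SA/TS2SA add
        self-activation on one/both genes; CTS is a chain of ``k`` coupled
        toggle switches; REPRESSILATOR is the 3-gene inhibition cycle;
        EMT22 is the 22-node epithelial-mesenchymal transition circuit.
    k : switch count for CTS (2..5 typical; larger allowed with a warning).
    """
    key = name.upper().replace("-", "").replace("_", "")
    if key == "TS":
        return _ts()
    if key == "TS1SA":
        return _ts("TS1SA", self_act=("A",))
    if key == "TS2SA":
        return _ts("TS2SA", self_act=("A", "B"))
    if key == "CTS":
        if k is None:
            raise ValueError("CTS requires the switch count k")
        return _coupled_toggle_switches(k)
    if key == "REPRESSILATOR":
        return _repressilator()
    if key == "EMT22":
        return _emt22()
    raise ValueError(f"unknown builtin circuit {name!r}; "
                     f"choose from {BUILTIN_CIRCUITS}")
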