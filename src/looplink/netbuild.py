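"""Residue-level cross-link structural networks.

A structural network has one node per residue (1..L) and two edge types:
backbone edges joining sequence-adjacent residues, and one cross-link
edge per unique observed site pair.  Backbone edges carry the covalent
chain geometry (3.8 A Calpha spacing in physical mode); cross-link edges
carry either a uniform display length, the DSBU linker span (26-30 A
between Calpha atoms), or a per-pair distance taken from an atomic model.
Observation multiplicities are kept as edge attributes — the graph stays
simple, which is what loop extraction and similarity operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import networkx as nx

from .exceptions import BoundsError, FormatError
from .xl_io import CrossLinkSet

if TYPE_CHECKING:  # pragma: no cover
    from .structmap import StructureModel

logger = logging.getLogger(__name__)

#: Calpha-Calpha span of the DSBU cross-linker, in Angstrom.
DSBU_SPAN = (26.0, 30.0)
#: Calpha-Calpha distance of sequence-adjacent residues, in Angstrom.
BACKBONE_SPACING = 3.8


@dataclass(frozen=True)
class NetworkConfig:
    """Edge-weight policy for a structural network.

    weight_mode:
      * ``uniform``       — fixed weights (display convention: backbone 1,
                            cross-link 8);
      * ``linker_span``   — backbone 3.8 A, cross-links the midpoint of
                            ``crosslink_range`` (DSBU: 28 A);
      * ``model_distance``— per-pair Calpha distances from a supplied
                            :class:`~looplink.structmap.StructureModel`,
                            falling back to the linker-span midpoint for
                            unmappable pairs (logged).
    """

    backbone_weight: float = 1.0
    crosslink_weight: float = 8.0
    crosslink_range: tuple[float, float] = DSBU_SPAN
    weight_mode: str = "uniform"

    def __post_init__(self) -> None:
        if self.backbone_weight <= 0 or self.crosslink_weight <= 0:
            raise ValueError("edge weights must be positive")
        lo, hi = self.crosslink_range
        if not 0 < lo <= hi:
            raise ValueError("crosslink_range must satisfy 0 < lo <= hi")
        if self.weight_mode not in {"uniform", "linker_span", "model_distance"}:
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")

    @classmethod
    def visualization(cls) -> "NetworkConfig":
        """Display convention: backbone length 1, cross-link length 8."""
        return cls(backbone_weight=1.0, crosslink_weight=8.0, weight_mode="uniform")

    @classmethod
    def physical(cls) -> "NetworkConfig":
        """Physical convention: backbone 3.8 A, cross-links the DSBU span."""
        return cls(backbone_weight=BACKBONE_SPACING, crosslink_weight=28.0,
                   crosslink_range=DSBU_SPAN, weight_mode="linker_span")


@dataclass
class StructuralNetwork:
    """Residues 1..L joined by backbone and unique cross-link edges."""

    graph: nx.Graph
    L: int
    protein_id: str = ""
    n_adjacent_dropped: int = field(default=0, compare=False)

    @property
    def backbone_edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v))
            for u, v, t in self.graph.edges(data="type") if t == "backbone"
        )

    @property
    def crosslink_edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v))
            for u, v, t in self.graph.edges(data="type") if t == "crosslink"
        )

    def multiplicity(self, i: int, j: int) -> int:
        return int(self.graph.edges[i, j]["multiplicity"])

    def without_crosslink(self, pair: tuple[int, int]) -> "StructuralNetwork":
        """A copy of the network with one cross-link edge removed."""
        g = self.graph.copy()
        g.remove_edge(*pair)
        return StructuralNetwork(graph=g, L=self.L, protein_id=self.protein_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructuralNetwork):
            return NotImplemented
        if (self.L, self.protein_id) != (other.L, other.protein_id):
            return False
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        mine = {tuple(sorted(e)): dict(d) for *e, d in self.graph.edges(data=True)}
        theirs = {tuple(sorted(e)): dict(d) for *e, d in other.graph.edges(data=True)}
        return mine == theirs


def build_network(
    L: int,
    xls: CrossLinkSet,
    config: NetworkConfig = NetworkConfig(),
    model: "StructureModel | None" = None,
    chain: str | None = None,
    offset: int = 0,
) -> StructuralNetwork:
    """Build the structural network for a protein of length L.

    Cross-links between sequence-adjacent residues (|i-j| == 1) duplicate
    backbone edges and are dropped with a logged count; loop extraction
    requires |i-j| >= 2.
    """
    if L < 2:
        raise ValueError("need at least two residues")
    g = nx.Graph()
    g.add_nodes_from(range(1, L + 1))
    for i in range(1, L):
        g.add_edge(i, i + 1, type="backbone", weight=float(config.backbone_weight),
                   multiplicity=1)

    lo, hi = config.crosslink_range
    midpoint = 0.5 * (lo + hi)
    n_adjacent = 0
    n_fallback = 0
    for (i, j) in sorted(xls.pairs):
        if j > L or i < 1:
            raise BoundsError(f"cross-link pair {(i, j)} outside residues 1..{L}")
        if j - i < 2:
            n_adjacent += 1
            continue
        if config.weight_mode == "uniform":
            w = float(config.crosslink_weight)
        elif config.weight_mode == "linker_span":
            w = midpoint
        else:  # model_distance
            w = None
            if model is not None:
                w = model.distance(i + offset, j + offset, chain=chain)
            if w is None:
                w = midpoint
                n_fallback += 1
        g.add_edge(i, j, type="crosslink", weight=float(w),
                   multiplicity=int(xls.pairs[(i, j)]))
    if n_adjacent:
        logger.info("build_network[%s]: dropped %d sequence-adjacent cross-links",
                    xls.protein_id, n_adjacent)
    if n_fallback:
        logger.info("build_network[%s]: %d pairs missing from model, "
                    "fell back to linker-span midpoint", xls.protein_id, n_fallback)
    return StructuralNetwork(graph=g, L=L, protein_id=xls.protein_id,
                             n_adjacent_dropped=n_adjacent)


def export_gml(net: StructuralNetwork, path: str | Path) -> None:
    """Write the network as GML with stable attribute order."""
    g = nx.Graph()
    g.graph["proteinId"] = net.protein_id
    g.graph["L"] = net.L
    for n in sorted(net.graph.nodes):
        g.add_node(n)
    for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
        d = net.graph.edges[u, v]
        g.add_edge(u, v, type=d["type"], weight=float(d["weight"]),
                   multiplicity=int(d["multiplicity"]))
    nx.write_gml(g, str(path))


def import_gml(path: str | Path) -> StructuralNetwork:
    """Read a network written by :func:`export_gml` (round-trip identity)."""
    try:
        g = nx.read_gml(str(path), label="label")
    except Exception as exc:
        raise FormatError(f"{path}: not a readable GML file ({exc})") from exc
    out = nx.Graph()
    for n in g.nodes:
        out.add_node(int(n))
    for u, v, d in g.edges(data=True):
        out.add_edge(int(u), int(v), type=str(d["type"]), weight=float(d["weight"]),
                     multiplicity=int(d["multiplicity"]))
    L = int(g.graph.get("L", max(out.nodes)))
    return StructuralNetwork(graph=out, L=L,
                             protein_id=str(g.graph.get("proteinId", "")))
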