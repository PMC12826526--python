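"""Mapping cross-links onto atomic structures and embedding networks in 3D.

Cross-links imply Calpha-Calpha distance constraints.  When a crystal
structure or structure model is available, each observed site pair is
mapped to the Euclidean distance between the corresponding Calpha atoms
and classified against a plausibility threshold (default 40 A — beyond
the ~30 A maximum span of DSBU plus allowance for flexibility).

Independently of any atomic model, the structural network itself can be
embedded in 3D with a seeded force-directed (spring) layout whose edge
target lengths follow the network's weights (backbone 3.8 A, cross-links
the linker span).  Rescaling the embedding to preserve the mean backbone
spacing and measuring the radius of gyration turns the embedding into a
network-level compactness estimate comparable to the Rg of an atomic
structure.  The embedding is an abstract, topology-preserving layout,
not an atomistic model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ContractError, FormatError
from .netbuild import BACKBONE_SPACING, StructuralNetwork

logger = logging.getLogger(__name__)

#: Distance-constraint plausibility threshold, in Angstrom.
DEFAULT_THRESHOLD = 40.0


@dataclass(frozen=True)
class StructureModel:
    """Calpha coordinates of a structure, keyed by (chain, residue number)."""

    source_id: str
    coords: Mapping[tuple[str, int], np.ndarray]

    def distance(self, res_a: int, res_b: int, chain: str | None = None) -> float | None:
        """Calpha-Calpha distance in A, or None if either residue is absent."""
        if chain is None:
            chain = next(iter(self.coords))[0] if self.coords else ""
        a = self.coords.get((chain, res_a))
        b = self.coords.get((chain, res_b))
        if a is None or b is None:
            return None
        return float(np.linalg.norm(a - b))

    def chain_coords(self, chain: str) -> np.ndarray:
        """All Calpha coordinates of one chain, in residue-number order."""
        keys = sorted(k for k in self.coords if k[0] == chain)
        return np.array([self.coords[k] for k in keys])


@dataclass(frozen=True)
class DistanceConstraint:
    """One cross-link mapped to a structure distance."""

    pair: tuple[int, int]
    distance: float
    flag: str  # "within" | "beyond"


@dataclass(frozen=True)
class ConstraintMapping:
    """Mapped constraints plus the pairs that could not be mapped."""

    constraints: tuple[DistanceConstraint, ...]
    skipped: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class DistanceStats:
    n: int
    mean: float
    sd: float
    p95: float


@dataclass(frozen=True)
class LayoutConfig:
    """Seeded 3D spring-layout parameters."""

    dimensions: int = 3
    iterations: int = 1000
    seed: int = 27061971

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class RgSimConfig:
    """Network-compactness simulation parameters.

    Each simulation assigns every cross-link edge a length drawn
    uniformly from a range, embeds the network in 3D and rescales node
    positions so the mean backbone neighbour distance is exactly the
    backbone length (3.8 A); the radius of gyration of the embedded
    nodes summarises compactness.  ``crosslink_ranges`` sweeps several
    length ranges, 20 simulations each by default.
    """

    backbone_length: float = BACKBONE_SPACING
    crosslink_ranges: tuple[tuple[float, float], ...] = ((26.0, 30.0),)
    n_sim: int = 20
    layout: LayoutConfig = field(default_factory=LayoutConfig)

    def __post_init__(self) -> None:
        for lo, hi in self.crosslink_ranges:
            if lo > hi:
                raise ValueError("crosslink range must satisfy lo <= hi")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")


@dataclass(frozen=True)
class RgSimResult:
    """Per-range Rg samples and their summary statistics."""

    ranges: tuple[tuple[float, float], ...]
    rg_values: tuple[tuple[float, ...], ...]  # one tuple of n_sim values per range

    def summary(self) -> list[dict[str, float]]:
        return [
            {"lo": lo, "hi": hi,
             "mean": float(np.mean(vals)), "sd": float(np.std(vals))}
            for (lo, hi), vals in zip(self.ranges, self.rg_values)
        ]

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for (lo, hi), vals in zip(self.ranges, self.rg_values):
            for k, v in enumerate(vals):
                rows.append({"range_lo": lo, "range_hi": hi, "sim": k, "rg": v})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_calpha(path: str | Path, chain: str) -> StructureModel:
    """Read one Calpha per residue of a chain from a PDB or mmCIF file.

    Alternate locations resolve to the highest-occupancy conformer;
    residues without a Calpha are simply absent from the map.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    suffix = path.suffix.lower()
    parser = MMCIFParser(QUIET=True) if suffix in {".cif", ".mmcif"} else PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:
        raise FormatError(f"{path}: could not parse structure ({exc})") from exc
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise LookupError(
            f"{path}: chain {chain!r} not found (available: "
            f"{[c.id for c in model]})"
        )
    coords: dict[tuple[str, int], np.ndarray] = {}
    n_gaps = 0
    for residue in model[chain]:
        hetflag, resnum, _ = residue.id
        if hetflag.strip():
            continue
        if "CA" not in residue:
            n_gaps += 1
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy())
        coords[(chain, int(resnum))] = np.asarray(atom.get_coord(), dtype=float)
    if n_gaps:
        logger.info("read_calpha[%s:%s]: %d residues without Calpha", path.name,
                    chain, n_gaps)
    return StructureModel(source_id=path.stem, coords=coords)


def map_constraints(
    model: StructureModel,
    pairs: Iterable[tuple[int, int]],
    chain: str | None = None,
    offset: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> ConstraintMapping:
    """Map site pairs to Calpha distance constraints.

    ``offset`` converts sequence numbering to structure numbering
    (structure_number = site + offset).  Pairs with either residue
    missing from the model are skipped and logged.
    """
    constraints: list[DistanceConstraint] = []
    skipped: list[tuple[int, int]] = []
    for (i, j) in pairs:
        d = model.distance(i + offset, j + offset, chain=chain)
        if d is None:
            skipped.append((i, j))
            continue
        flag = "within" if d < threshold else "beyond"
        constraints.append(DistanceConstraint(pair=(i, j), distance=d, flag=flag))
    if skipped:
        logger.info("map_constraints[%s]: skipped %d/%d unmappable pairs",
                    model.source_id, len(skipped),
                    len(skipped) + len(constraints))
    return ConstraintMapping(constraints=tuple(constraints), skipped=tuple(skipped))


def write_constraints_tsv(mapping: ConstraintMapping, path: str | Path) -> None:
    pd.DataFrame(
        [{"site_a": c.pair[0], "site_b": c.pair[1],
          "distance_A": c.distance, "flag": c.flag}
         for c in mapping.constraints]
    ).to_csv(path, sep="\t", index=False)


def distance_stats(constraints: Sequence[DistanceConstraint] | Sequence[float]) -> DistanceStats:
    """Mean, population sd and linearly interpolated 95th percentile."""
    if len(constraints) == 0:
        raise ContractError("distance_stats needs at least one constraint")
    if isinstance(constraints[0], DistanceConstraint):
        d = np.array([c.distance for c in constraints])
    else:
        d = np.asarray(constraints, dtype=float)
    return DistanceStats(
        n=len(d),
        mean=float(d.mean()),
        sd=float(d.std()),  # population sd
        p95=float(np.percentile(d, 95.0)),  # linear interpolation
    )


def radius_of_gyration(coords: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Root-mean-square distance of points from their centroid."""
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    if pts.size == 0:
        raise ContractError("radius_of_gyration needs at least one point")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum(axis=1).mean()))


def layout3d(
    net: StructuralNetwork,
    config: LayoutConfig = LayoutConfig(),
    rescale: bool = True,
) -> dict[int, np.ndarray]:
    """Seeded 3D force-directed embedding with per-edge target lengths.

    Edge target lengths are the network's edge weights.  The layout is a
    Fruchterman-Reingold spring embedding (networkx) where the spring
    attraction of each edge is the reciprocal of its target length, so
    short-target edges pull their endpoints closer; a fixed seed makes
    the embedding bitwise reproducible.  With ``rescale`` the coordinates
    are scaled globally so the mean ratio of realized to target edge
    length is one.
    """
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    targets: dict[tuple[int, int], float] = {}
    for u, v, d in net.graph.edges(data=True):
        target = float(d["weight"])
        g.add_edge(u, v, spring=1.0 / target)
        targets[(u, v)] = target
    pos = nx.spring_layout(
        g, dim=config.dimensions, iterations=config.iterations,
        seed=config.seed, weight="spring",
    )
    coords = {n: np.asarray(p, dtype=float) for n, p in pos.items()}
    if rescale and targets:
        ratios = [
            np.linalg.norm(coords[u] - coords[v]) / t
            for (u, v), t in targets.items()
        ]
        mean_ratio = float(np.mean(ratios))
        if mean_ratio > 0:
            scale = 1.0 / mean_ratio
            coords = {n: p * scale for n, p in coords.items()}
    return coords


def rescale_to_backbone(
    coords: dict[int, np.ndarray],
    net: StructuralNetwork,
    backbone_length: float = BACKBONE_SPACING,
) -> dict[int, np.ndarray]:
    """Globally scale an embedding so mean backbone spacing equals 3.8 A."""
    spacings = [
        np.linalg.norm(coords[i] - coords[j]) for i, j in net.backbone_edges
    ]
    mean_spacing = float(np.mean(spacings))
    if mean_spacing == 0:
        raise ContractError("degenerate embedding: zero backbone spacing")
    scale = backbone_length / mean_spacing
    return {n: p * scale for n, p in coords.items()}


def simulate_rg(
    net: StructuralNetwork,
    config: RgSimConfig = RgSimConfig(),
    rng: np.random.Generator | None = None,
) -> RgSimResult:
    """Compactness of the network under randomized cross-link lengths.

    Per simulation each cross-link edge gets a length ~ Uniform[lo, hi],
    backbone edges the fixed backbone length; the network is embedded in
    3D, rescaled to the mean backbone spacing, and its Rg recorded.
    """
    if rng is None:
        rng = np.random.default_rng()
    xl_edges = net.crosslink_edges
    per_range: list[tuple[float, ...]] = []
    for lo, hi in config.crosslink_ranges:
        values: list[float] = []
        for _ in range(config.n_sim):
            g = net.graph.copy()
            for i, j in net.backbone_edges:
                g.edges[i, j]["weight"] = config.backbone_length
            for i, j in xl_edges:
                g.edges[i, j]["weight"] = float(rng.uniform(lo, hi))
            sim_net = StructuralNetwork(graph=g, L=net.L, protein_id=net.protein_id)
            layout_seed = int(rng.integers(0, 2**31 - 1))
            layout_cfg = LayoutConfig(
                dimensions=config.layout.dimensions,
                iterations=config.layout.iterations,
                seed=layout_seed,
            )
            coords = layout3d(sim_net, layout_cfg, rescale=False)
            coords = rescale_to_backbone(coords, sim_net, config.backbone_length)
            values.append(radius_of_gyration(np.array(list(coords.values()))))
        per_range.append(tuple(values))
    return RgSimResult(ranges=tuple(config.crosslink_ranges),
                       rg_values=tuple(per_range))


def export_embedding_tsv(
    coords: dict[int, np.ndarray],
    path: str | Path,
    scores: Mapping[int, float] | None = None,
) -> None:
    """Write embedding coordinates (and optional per-residue scores) as TSV."""
    rows = []
    for n in sorted(coords):
        row = {"residue": n, "x": coords[n][0], "y": coords[n][1],
               "z": coords[n][2] if len(coords[n]) > 2 else 0.0}
        if scores is not None:
            row["score"] = scores.get(n, math.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_embedding(
    coords: dict[int, np.ndarray],
    net: StructuralNetwork,
    path: str | Path,
    scores: Mapping[int, float] | None = None,
    annotate_every: int = 10,
) -> None:
    """Static 3D rendering: backbone blue, cross-links red, nodes colored
    by per-residue similarity (plasma colormap) when scores are given;
    every ``annotate_every``-th node is labelled."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for i, j in net.backbone_edges:
        seg = np.array([coords[i], coords[j]])
        ax.plot(*seg.T, color="tab:blue", lw=0.6, alpha=0.7)
    for i, j in net.crosslink_edges:
        seg = np.array([coords[i], coords[j]])
        ax.plot(*seg.T, color="tab:red", lw=0.8, alpha=0.8)
    nodes = sorted(coords)
    pts = np.array([coords[n] for n in nodes])
    c = [scores.get(n, 0.5) for n in nodes] if scores is not None else "k"
    sc = ax.scatter(*pts.T, c=c, cmap="plasma", s=8, vmin=0, vmax=1)
    if scores is not None:
        fig.colorbar(sc, ax=ax, shrink=0.6, label="element-centric similarity")
    for n in nodes:
        if n % annotate_every == 0:
            ax.text(*coords[n], str(n), fontsize=5)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
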