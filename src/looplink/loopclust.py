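"""Loop extraction: the overlapping clustering induced by cross-links.

Every cross-link between non-adjacent residues closes a cycle with the
backbone: the cross-link edge plus the (unique) backbone path between
its endpoints.  The enclosed contiguous sequence segment {i..j} is a
*loop* — a constrained structural motif analogous to a folding unit
bounded by the cross-linked residues.  Because loops share residues,
the collection of loop memberships forms a soft (overlapping)
clustering of the sequence.  Residues covered by no loop are kept as
singleton clusters so that two clusterings being compared always share
the same element universe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .netbuild import StructuralNetwork


@dataclass(frozen=True)
class Loop:
    """The contiguous backbone interval enclosed by one cross-link."""

    closing_pair: tuple[int, int]
    members: tuple[int, ...]

    def __post_init__(self) -> None:
        i, j = self.closing_pair
        if self.members != tuple(range(i, j + 1)):
            raise ValueError(f"loop members must be the interval {i}..{j}")
        if len(self.members) < 3:
            raise ValueError("a loop spans at least three residues (|i-j| >= 2)")


@dataclass(frozen=True)
class LoopClustering:
    """Overlapping clustering of residues 1..L into loops and singletons.

    ``clusters`` lists loop clusters first (sorted by closing pair), then
    singleton clusters for uncovered residues (sorted by residue).
    ``membership`` maps every residue to the ids of the clusters that
    contain it; ids index into ``clusters``.
    """

    universe_size: int
    clusters: tuple[tuple[int, ...], ...]
    loop_pairs: tuple[tuple[int, int] | None, ...]
    membership: dict[int, tuple[int, ...]]

    @property
    def n_loops(self) -> int:
        return sum(1 for p in self.loop_pairs if p is not None)

    @property
    def n_singletons(self) -> int:
        return len(self.clusters) - self.n_loops

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "universe_size": self.universe_size,
            "clusters": [
                {
                    "id": cid,
                    "type": "loop" if pair is not None else "singleton",
                    **({"closing_pair": list(pair)} if pair is not None else {}),
                    "members": list(members),
                }
                for cid, (members, pair) in enumerate(zip(self.clusters, self.loop_pairs))
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def extract_loops(net: StructuralNetwork) -> LoopClustering:
    """Extract the loop-based overlapping clustering of a network.

    The backbone subgraph is a path graph, so the backbone shortest path
    between the endpoints of a cross-link (i, j) is exactly the interval
    i..j; cross-link edges are never used as shortcuts inside another
    loop.  One loop per unique cross-link edge; uncovered residues become
    singletons.  Output is deterministic: loops sorted by (i, j).
    """
    L = net.L
    loops = sorted(net.crosslink_edges)
    clusters: list[tuple[int, ...]] = []
    loop_pairs: list[tuple[int, int] | None] = []
    membership: dict[int, list[int]] = {r: [] for r in range(1, L + 1)}
    for cid, (i, j) in enumerate(loops):
        members = tuple(range(i, j + 1))
        clusters.append(members)
        loop_pairs.append((i, j))
        for r in members:
            membership[r].append(cid)
    uncovered = [r for r in range(1, L + 1) if not membership[r]]
    for r in uncovered:
        cid = len(clusters)
        clusters.append((r,))
        loop_pairs.append(None)
        membership[r].append(cid)
    return LoopClustering(
        universe_size=L,
        clusters=tuple(clusters),
        loop_pairs=tuple(loop_pairs),
        membership={r: tuple(ids) for r, ids in membership.items()},
    )


def clustering_from_members(universe_size: int,
                            clusters: list[tuple[int, ...]]) -> LoopClustering:
    """Build a LoopClustering from explicit member lists (testing/interop).

    Clusters are taken as given; residues in no cluster become singletons.
    """
    membership: dict[int, list[int]] = {r: [] for r in range(1, universe_size + 1)}
    out_clusters: list[tuple[int, ...]] = []
    loop_pairs: list[tuple[int, int] | None] = []
    for members in clusters:
        cid = len(out_clusters)
        out_clusters.append(tuple(members))
        loop_pairs.append(None)
        for r in members:
            membership[r].append(cid)
    for r in range(1, universe_size + 1):
        if not membership[r]:
            cid = len(out_clusters)
            out_clusters.append((r,))
            loop_pairs.append(None)
            membership[r].append(cid)
    return LoopClustering(
        universe_size=universe_size,
        clusters=tuple(out_clusters),
        loop_pairs=tuple(loop_pairs),
        membership={r: tuple(ids) for r, ids in membership.items()},
    )
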