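"""Chlorophyll excitation-pathway network.

Chlorophylls are represented by their Mg atoms; two sites are connected
when their Mg-Mg distance is at most the cutoff (23 Å by default, a
practical upper bound for inter-pigment excitation transfer).  Edge
weights decrease linearly with distance (``cutoff - distance``), mirroring
the convention of drawing closer pairs with wider lines.  The threshold is
closed: a pair at exactly the cutoff is connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .model import StructureModel


@dataclass(frozen=True)
class PigmentNode:
    site: tuple[str, int, str]       # (chain_id, auth_seq_id, comp_code)
    mg_pos: tuple[float, float, float]
    chain_id: str
    group_id: Optional[str] = None


@dataclass
class PigmentEdge:
    a: PigmentNode
    b: PigmentNode
    distance: float
    inter_subunit: bool
    inter_group: bool

    @property
    def width_weight(self) -> float:
        return self._cutoff - self.distance

    _cutoff: float = 23.0


@dataclass
class PigmentGraph:
    nodes: list[PigmentNode]
    edges: list[PigmentEdge]
    cutoff: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _edge_key(a: PigmentNode, b: PigmentNode):
    return tuple(sorted((a.site, b.site)))


def build_network(model: StructureModel, cutoff: float = 23.0,
                  grouping: Optional[dict[str, str]] = None,
                  use_kdtree: bool = True) -> PigmentGraph:
    """Mg-Mg distance graph over all chlorophylls.

    ``grouping`` maps chain_id to a group label (e.g. the two monomers of a
    dimer); edges between groups carry ``inter_group=True``.  The KD-tree
    path is bit-identical to the brute-force all-pairs scan
    (:func:`brute_force_edges`).
    """
    chls = [r for r in model.chlorophylls() if r.mg is not None]
    nodes = [PigmentNode(r.site, tuple(map(float, r.mg.pos)), r.chain_id,
                         grouping.get(r.chain_id) if grouping else None)
             for r in chls]
    edges: list[PigmentEdge] = []
    if len(nodes) >= 2:
        pts = np.array([n.mg_pos for n in nodes])
        if use_kdtree:
            pairs = sorted(cKDTree(pts).query_pairs(cutoff))
        else:
            pairs = [(i, j) for i in range(len(nodes))
                     for j in range(i + 1, len(nodes))
                     if np.linalg.norm(pts[i] - pts[j]) <= cutoff]
        for i, j in pairs:
            d = float(np.linalg.norm(pts[i] - pts[j]))
            if d > cutoff:
                continue
            a, b = nodes[i], nodes[j]
            edges.append(PigmentEdge(
                a, b, d,
                inter_subunit=a.chain_id != b.chain_id,
                inter_group=(a.group_id is not None
                             and b.group_id is not None
                             and a.group_id != b.group_id),
                _cutoff=cutoff))
    edges.sort(key=lambda e: _edge_key(e.a, e.b))
    return PigmentGraph(nodes, edges, cutoff)


def brute_force_edges(model: StructureModel,
                      cutoff: float = 23.0) -> set[tuple]:
    """All-pairs O(n^2) oracle: the set of edge keys at the cutoff."""
    chls = [r for r in model.chlorophylls() if r.mg is not None]
    out = set()
    for i in range(len(chls)):
        for j in range(i + 1, len(chls)):
            if np.linalg.norm(chls[i].mg.pos - chls[j].mg.pos) <= cutoff:
                out.add(tuple(sorted((chls[i].site, chls[j].site))))
    return out


def inter_group_edges(graph: PigmentGraph,
                      grouping: Optional[dict[str, str]] = None
                      ) -> list[PigmentEdge]:
    """Cross-group edges, sorted by distance.

    When ``grouping`` is given it overrides the node group labels; every
    chain bearing a chlorophyll must then be mapped.
    """
    if grouping is not None:
        unmapped = sorted({n.chain_id for n in graph.nodes
                           if n.chain_id not in grouping})
        if unmapped:
            raise KeyError("grouping misses chlorophyll-bearing chains: "
                           + ", ".join(unmapped))

        def crosses(e: PigmentEdge) -> bool:
            return grouping[e.a.chain_id] != grouping[e.b.chain_id]
    else:
        def crosses(e: PigmentEdge) -> bool:
            return e.inter_group
    return sorted((e for e in graph.edges if crosses(e)),
                  key=lambda e: e.distance)


def likely_inter_subunit_pathways(graph: PigmentGraph) -> list[PigmentEdge]:
    """Per chain pair, the minimum-distance inter-subunit edge — the most
    plausible excitation route between two subunits under a
    distance-only model."""
    best: dict[tuple[str, str], PigmentEdge] = {}
    for e in graph.edges:
        if not e.inter_subunit:
            continue
        key = tuple(sorted((e.a.chain_id, e.b.chain_id)))
        if key not in best or e.distance < best[key].distance:
            best[key] = e
    return sorted(best.values(), key=lambda e: e.distance)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _node_id(n: PigmentNode) -> str:
    return f"{n.site[0]}/{n.site[2]}{n.site[1]}"


def export_graph(graph: PigmentGraph, path: str | Path,
                 format: str = "edge_tsv") -> Path:
    path = Path(path)
    if format == "edge_tsv":
        lines = ["chain_a\tres_a\tchain_b\tres_b\tdistance\t"
                 "inter_subunit\tinter_group"]
        for e in graph.edges:
            lines.append(f"{e.a.site[0]}\t{e.a.site[2]}{e.a.site[1]}\t"
                         f"{e.b.site[0]}\t{e.b.site[2]}{e.b.site[1]}\t"
                         f"{e.distance:.3f}\t{int(e.inter_subunit)}\t"
                         f"{int(e.inter_group)}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        import networkx as nx
        g = nx.Graph(cutoff=graph.cutoff)
        for n in graph.nodes:
            g.add_node(_node_id(n), chain_id=n.chain_id,
                       group_id=n.group_id or "",
                       x=n.mg_pos[0], y=n.mg_pos[1], z=n.mg_pos[2])
        for e in graph.edges:
            g.add_edge(_node_id(e.a), _node_id(e.b),
                       distance=round(e.distance, 3),
                       inter_subunit=int(e.inter_subunit),
                       inter_group=int(e.inter_group))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def read_edge_tsv(path: str | Path) -> list[tuple[str, str, float]]:
    """Re-read an exported edge TSV (endpoint ids and distances)."""
    out = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        ca, ra, cb, rb, d, _, _ = line.split("\t")
        out.append((f"{ca}/{ra}", f"{cb}/{rb}", float(d)))
    return out
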