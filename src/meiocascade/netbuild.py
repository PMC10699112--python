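"""Phase network reconstruction: PPIN, GRN, integration and MR calling.

The integrated cascade is a directed graph combining regulatory edges
(TF->TF, TF->TG) with reciprocal directed pairs for physical interactions
between non-TF genes (TG-TG). Node hierarchy is summarized by
v = (out - in) / (out + in); transcription factors at v = 1 are called
master regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "RegulatoryNetwork",
    "CascadeNode",
    "IntegratedCascade",
    "build_ppin",
    "build_grn",
    "top_tfs",
    "integrate_cascade",
    "hierarchy_index",
    "identify_mrs",
]


class InteractionNetwork:
    """Undirected physical-interaction network (no self-loops, no duplicates)."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self.graph = nx.Graph()
        for a, b in edges:
            if a == b:
                continue  # self-interactions carry no hierarchy information
            self.graph.add_edge(a, b)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def __len__(self) -> int:
        return self.graph.number_of_edges()


class RegulatoryNetwork:
    """Directed TF -> target binding network."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self._edges: set[tuple[str, str]] = set()
        for tf, target in edges:
            self._edges.add((tf, target))

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._edges)

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self._edges}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self._edges}

    @property
    def nodes(self) -> set[str]:
        return self.tfs | self.targets

    def out_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for tf, _ in self._edges:
            counts[tf] = counts.get(tf, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self._edges)


@dataclass(frozen=True)
class CascadeNode:
    gene_id: str
    in_deg: int
    out_deg: int
    v: float
    role: str  # MR | TF | TG


@dataclass
class IntegratedCascade:
    nodes: dict[str, CascadeNode]
    edges: list[tuple[str, str, str]]  # (source, target, layer)
    tf_ids: set[str] = field(default_factory=set)

    def mr_ids(self) -> set[str]:
        return {g for g, n in self.nodes.items() if n.role == "MR"}


def build_ppin(
    seed_genes: set[str],
    global_interactions: InteractionNetwork,
    expand_neighbors: bool = True,
) -> InteractionNetwork:
    """Induce the interaction subnetwork on seeds (optionally + first neighbors)."""
    if not seed_genes:
        raise ValueError("seed_genes is empty")
    g = global_interactions.graph
    present = seed_genes & set(g.nodes)
    if not present:
        raise ValueError("no seed gene occurs in the global interaction network")
    keep = set(present)
    if expand_neighbors:
        for gene in present:
            keep.update(g.neighbors(gene))
    sub = g.subgraph(keep)
    isolated = [n for n in present if sub.degree(n) == 0]
    if isolated:
        logger.info("dropping %d isolated seed genes", len(isolated))
    edges = [e for e in sub.edges]
    if not edges:
        raise ValueError("induced interaction network has no edges")
    return InteractionNetwork(edges)


def build_grn(
    target_genes: set[str], binding_table: RegulatoryNetwork
) -> RegulatoryNetwork:
    """Restrict a TF-binding table to edges whose target is in target_genes."""
    if not target_genes:
        raise ValueError("target_genes is empty")
    edges = [(tf, t) for tf, t in binding_table.edges if t in target_genes]
    if not edges:
        raise ValueError("no TF in the binding table targets any target gene")
    return RegulatoryNetwork(edges)


def top_tfs(grn: RegulatoryNetwork) -> tuple[set[str], float]:
    """TFs whose target count strictly exceeds the mean target count."""
    counts = grn.out_counts()
    if not counts:
        raise ValueError("GRN has no TFs")
    cutoff = sum(counts.values()) / len(counts)
    top = {tf for tf, c in counts.items() if c > cutoff}
    logger.info("top TFs: %d of %d above cutoff %.2f", len(top), len(counts), cutoff)
    return top, cutoff


def hierarchy_index(in_deg: int, out_deg: int) -> float:
    """(out - in) / (out + in); undefined (error) for isolated nodes."""
    total = in_deg + out_deg
    if total < 1:
        raise ValueError("hierarchy index undefined for isolated node (0, 0)")
    return (out_deg - in_deg) / total


def integrate_cascade(
    grn: RegulatoryNetwork, ppin: InteractionNetwork
) -> IntegratedCascade:
    """Merge TF->TF / TF->TG regulatory edges with reciprocal TG-TG pairs.

    Physical edges between two non-TF genes enter as reciprocal directed
    pairs; physical edges touching a TF are excluded (they are not part of
    the TG-TG layer). TF self-loops are dropped so autoregulation does not
    disqualify an otherwise apex regulator.
    """
    tf_ids = grn.tfs
    edge_layer: dict[tuple[str, str], str] = {}
    for tf, target in grn.edges:
        if tf == target:
            continue  # autoregulatory self-loop dropped
        layer = "TF-TF" if target in tf_ids else "TF-TG"
        edge_layer.setdefault((tf, target), layer)
    for a, b in ppin.edges:
        if a in tf_ids or b in tf_ids:
            continue
        edge_layer.setdefault((a, b), "TG-TG")
        edge_layer.setdefault((b, a), "TG-TG")
    if not edge_layer:
        raise ValueError("integrated cascade is empty")

    in_deg: dict[str, int] = {}
    out_deg: dict[str, int] = {}
    for src, tgt in edge_layer:
        out_deg[src] = out_deg.get(src, 0) + 1
        in_deg[tgt] = in_deg.get(tgt, 0) + 1
        in_deg.setdefault(src, 0)
        out_deg.setdefault(tgt, 0)

    nodes: dict[str, CascadeNode] = {}
    for gene in in_deg:
        i, o = in_deg[gene], out_deg[gene]
        v = hierarchy_index(i, o)
        if gene in tf_ids and i == 0 and o >= 1:
            role = "MR"
        elif gene in tf_ids:
            role = "TF"
        else:
            role = "TG"
        nodes[gene] = CascadeNode(gene, i, o, v, role)
    edges = [(s, t, layer) for (s, t), layer in sorted(edge_layer.items())]
    return IntegratedCascade(nodes=nodes, edges=edges, tf_ids=set(tf_ids))


def identify_mrs(cascade: IntegratedCascade) -> set[str]:
    """TF nodes at the hierarchy apex (v exactly 1, out-degree >= 1)."""
    if not cascade.nodes:
        raise ValueError("cascade is empty")
    mrs = {
        g
        for g, n in cascade.nodes.items()
        if g in cascade.tf_ids and n.in_deg == 0 and n.out_deg >= 1
    }
    if not mrs:
        logger.warning("no node with hierarchy index 1; empty MR set")
    return mrs
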