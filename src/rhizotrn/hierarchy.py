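"""Hierarchy decomposition of a regulatory network.

Structural genes (out-connectivity zero) are removed in a single pass, each
remaining edge (a, b) is classified top-down when kout(a) > kout(b) and
bottom-up otherwise (ties included — a self-loop is therefore always
bottom-up), bottom-up edges are removed, and the resulting directed acyclic
graph is peeled into layers in which a node can only regulate nodes in
strictly lower layers.  Because bottom-up edges are few in regulatory
networks, the layering preserves the global top-down structure; adding the
removed edges and structural genes back reconstructs the original network
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "HierarchyResult",
    "strip_structural",
    "classify_edges",
    "layer_sort",
    "decompose",
]


@dataclass
class HierarchyResult:
    """Layers of regulators (layer 1 = top) plus everything removed on the way."""

    layers: list[set[str]]
    removed_bottom_up: list[tuple[str, str]]
    bottom_up_fraction: float
    structural_removed: set[str]
    isolated: set[str] = field(default_factory=set)

    def layer_of(self) -> dict[str, int]:
        return {n: i + 1 for i, layer in enumerate(self.layers) for n in layer}


def strip_structural(g: nx.DiGraph) -> tuple[nx.DiGraph, set[str]]:
    """Remove nodes with out-connectivity zero, once (not to a fixed point)."""
    structural = {n for n, d in g.out_degree() if d == 0}
    reduced = g.copy()
    reduced.remove_nodes_from(structural)
    return reduced, structural


def classify_edges(
    g: nx.DiGraph,
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Split edges into top-down (kout(a) > kout(b)) and bottom-up (the rest).

    Out-connectivities are taken on the graph as given (i.e. after the
    structural pass); equal out-connectivities — including every self-loop —
    fall in the bottom-up class.
    """
    kout = dict(g.out_degree())
    top_down, bottom_up = set(), set()
    for a, b in g.edges:
        if kout[a] > kout[b]:
            top_down.add((a, b))
        else:
            bottom_up.add((a, b))
    return top_down, bottom_up


def layer_sort(dag: nx.DiGraph, isolated_to_bottom: bool = True) -> list[set[str]]:
    """Layers of a DAG: each node sits one layer below its deepest regulator.

    Layer 1 holds the roots (in-degree 0); every edge then runs from a
    strictly higher to a strictly lower layer.  Nodes with no edges at all
    are placed in the bottom layer (they carry no ordering information).
    A residual cycle is an internal error — callers must remove bottom-up
    edges first.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise RuntimeError("layer_sort requires an acyclic graph")
    connected = {n for e in dag.edges for n in e}
    depth: dict[str, int] = {}
    for n in nx.topological_sort(dag):
        if n not in connected:
            continue
        preds = [depth[p] for p in dag.predecessors(n)]
        depth[n] = 1 + max(preds, default=0)
    n_layers = max(depth.values(), default=0)
    isolated = set(dag.nodes) - connected
    if isolated and isolated_to_bottom:
        n_layers = max(n_layers, 1)
    layers = [set() for _ in range(n_layers)]
    for n, d in depth.items():
        layers[d - 1].add(n)
    if isolated_to_bottom and isolated:
        layers[-1] |= isolated
    return layers


def decompose(g: nx.DiGraph) -> HierarchyResult:
    """Full hierarchy reconstruction of a regulatory network."""
    reduced, structural = strip_structural(g)
    top_down, bottom_up = classify_edges(reduced)
    dag = reduced.copy()
    dag.remove_edges_from(bottom_up)
    layers = layer_sort(dag)
    connected = {n for e in dag.edges for n in e}
    isolated = set(dag.nodes) - connected
    classified = len(top_down) + len(bottom_up)
    frac = len(bottom_up) / classified if classified else 0.0
    return HierarchyResult(
        layers=layers,
        removed_bottom_up=sorted(bottom_up),
        bottom_up_fraction=frac,
        structural_removed=structural,
        isolated=isolated,
    )
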