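"""Hub-centered module network graphs with DE-group overlays.

For each co-expression module, the node set unions (1) the module's
differentially expressed proteins and (2) the top-k proteins most strongly
connected to the module hub in the signed adjacency, regardless of DE
status. Edge weights are adjacency values (a downstream layout can use
1/weight as edge length, so stronger co-expression draws nodes closer);
an optional adjacency-quantile floor prunes the near-complete graph for
legible exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .diffexp import DEGroups
from .wgcna import ModuleAssignment


@dataclass
class HubNetwork:
    module: str
    hub: str
    nodes: dict[str, str]  # protein -> group tag
    edges: list[tuple[str, str, float]]
    edge_floor: float = 0.0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(module=self.module, hub=self.hub)
        for node, tag in self.nodes.items():
            g.add_node(node, group=tag)
        for i, j, w in self.edges:
            g.add_edge(i, j, weight=float(w))
        return g


def _group_tag(protein: str, de_groups: DEGroups | None) -> str:
    if de_groups is None:
        return "background"
    if protein in de_groups.stepwise:
        return "stepwise"
    if protein in de_groups.unique:
        return "unique"
    if protein in de_groups.upregulated_ad:
        return "upregulated_ad"
    return "background"


def hub_network(
    module: str,
    assignment: ModuleAssignment,
    adjacency: pd.DataFrame,
    de_groups: DEGroups | None,
    hub: str,
    top_k: int = 30,
    edge_floor_quantile: float = 0.0,
) -> HubNetwork:
    """Build one module's hub graph.

    ``edge_floor_quantile`` is the within-node-set adjacency quantile below
    which non-hub edges are dropped (0 keeps the complete graph, matching
    the published construction); the hub keeps a direct edge to every node.
    """
    if module not in set(assignment.labels.values):
        raise ValueError(f"unknown module: {module!r}")
    if hub not in adjacency.index:
        raise ValueError(f"hub {hub!r} not in adjacency")
    members = assignment.members(module)
    de_all = (
        (de_groups.upregulated_ad | de_groups.stepwise | de_groups.unique)
        if de_groups is not None else set()
    )
    de_in_module = sorted(de_all & set(members))
    hub_adj = adjacency[hub].drop(index=hub).sort_values(ascending=False)
    top = list(hub_adj.index[:top_k])
    node_ids = sorted(set(de_in_module) | set(top) | {hub})
    nodes = {n: ("hub" if n == hub else _group_tag(n, de_groups)) for n in node_ids}

    sub = adjacency.loc[node_ids, node_ids]
    iu = np.triu_indices(len(node_ids), 1)
    upper = sub.to_numpy()[iu]
    floor = float(np.quantile(upper, edge_floor_quantile)) if len(upper) and edge_floor_quantile > 0 else 0.0
    edges: list[tuple[str, str, float]] = []
    for a_idx, b_idx in zip(*iu):
        a, b = node_ids[a_idx], node_ids[b_idx]
        w = float(sub.iat[a_idx, b_idx])
        if hub in (a, b) or w >= floor:
            edges.append((a, b, w))
    return HubNetwork(module=module, hub=hub, nodes=nodes, edges=edges, edge_floor=floor)


def export_graph(net: HubNetwork, path, format: str = "graphml") -> None:
    """Serialise nodes (id, group tag) and weighted edges losslessly."""
    g = net.to_networkx()
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for i, j, w in net.edges:
                fh.write(f"{i}\t{j}\t{w!r}\n")
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_graphml(path) -> HubNetwork:
    g = nx.read_graphml(path)
    nodes = {n: d.get("group", "background") for n, d in g.nodes(data=True)}
    edges = [(i, j, float(d["weight"])) for i, j, d in g.edges(data=True)]
    return HubNetwork(
        module=g.graph.get("module", ""),
        hub=g.graph.get("hub", ""),
        nodes=nodes,
        edges=edges,
    )
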