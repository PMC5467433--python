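"""Merging the pairwise networks and analyzing the merged topology.

The ten (in general C(B,2)) bipartite networks are merged into one simple
undirected typed graph; nodes present in fewer than two of the
contributing networks are dropped; topology metrics follow the
conventions of the motivating analysis, notably the characteristic path
length as the *median* over nodes of each node's mean shortest-path
distance to the others.  "Connectivity hubs" are nodes whose neighbors
span every data type other than their own.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import networkx as nx

from .association import PairwiseNetwork

__all__ = [
    "merge_networks",
    "filter_min_membership",
    "topology",
    "find_hubs",
    "TopologyReport",
    "HubSet",
]


def merge_networks(networks: list[PairwiseNetwork]) -> nx.Graph:
    """Union of the pairwise networks as one simple undirected graph.

    Node attributes: ``data_type`` and ``networks`` (the set of pairwise
    network names the node appeared in).  Edge attributes: ``weight``,
    ``sign`` and ``networks`` provenance; if the same unordered pair is
    contributed twice (possible only with user-supplied inputs sharing a
    type pair) the larger-|weight| contribution wins, provenance is kept.
    """
    if not networks:
        raise ValueError("cannot merge an empty list of networks")
    g = nx.Graph()
    for net in networks:
        for node, dtype in [
            *[(f, net.data_type_x) for f in net.nodes_x],
            *[(f, net.data_type_y) for f in net.nodes_y],
        ]:
            if node in g:
                if g.nodes[node]["data_type"] != dtype:
                    raise ValueError(
                        f"node {node!r} labelled both "
                        f"{g.nodes[node]['data_type']!r} and {dtype!r}"
                    )
                g.nodes[node]["networks"].add(net.name)
            else:
                g.add_node(node, data_type=dtype, networks={net.name})
        for fx, fy, w, s in net.edges:
            if g.has_edge(fx, fy):
                e = g.edges[fx, fy]
                e["networks"].add(net.name)
                if abs(w) > abs(e["weight"]):
                    e["weight"], e["sign"] = w, s
            else:
                g.add_edge(fx, fy, weight=w, sign=s, networks={net.name})
    return g


def filter_min_membership(merged: nx.Graph, k: int = 2) -> nx.Graph:
    """Keep nodes present in >= k of the original pairwise networks.

    A single pass: membership counts come from the original networks, so
    the filter is idempotent (nodes are not re-counted on the filtered
    graph).  Edges incident to removed nodes are dropped.
    """
    keep = [n for n, d in merged.nodes(data=True) if len(d["networks"]) >= k]
    return merged.subgraph(keep).copy()


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    nodes_per_type: dict[str, int]
    degree_min: int
    degree_max: int
    average_neighbors: float
    average_clustering: float
    characteristic_path_length: float
    density: float
    n_components: int

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "nodes_per_type": dict(self.nodes_per_type),
            "degree_min": self.degree_min,
            "degree_max": self.degree_max,
            "average_neighbors": self.average_neighbors,
            "average_clustering": self.average_clustering,
            "characteristic_path_length": self.characteristic_path_length,
            "density": self.density,
            "n_components": self.n_components,
        }


def characteristic_path_length(g: nx.Graph) -> float:
    """Median over nodes of the node's mean distance to reachable others.

    Unreachable pairs are excluded from a node's average; an isolated
    node contributes nothing to the median.
    """
    means = []
    for node in g:
        lengths = nx.single_source_shortest_path_length(g, node)
        del lengths[node]
        if lengths:
            means.append(sum(lengths.values()) / len(lengths))
    if not means:
        raise ValueError("graph has no connected node pairs")
    return float(statistics.median(means))


def topology(g: nx.Graph) -> TopologyReport:
    """Topology metrics of a simple undirected typed graph."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = dict(g.degree())
    per_type: dict[str, int] = {}
    for _, d in g.nodes(data=True):
        t = d.get("data_type", "untyped")
        per_type[t] = per_type.get(t, 0) + 1
    return TopologyReport(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        nodes_per_type=per_type,
        degree_min=min(degrees.values()),
        degree_max=max(degrees.values()),
        average_neighbors=sum(degrees.values()) / len(degrees),
        average_clustering=nx.average_clustering(g),
        characteristic_path_length=characteristic_path_length(g),
        density=nx.density(g),
        n_components=nx.number_connected_components(g),
    )


@dataclass
class HubSet:
    """Connectivity hubs and the data types each hub's neighbors cover."""

    hubs: set[str]
    coverage: dict[str, set[str]]  # node -> neighbor data types

    def __contains__(self, node: str) -> bool:
        return node in self.hubs

    def __len__(self) -> int:
        return len(self.hubs)


def find_hubs(g: nx.Graph) -> HubSet:
    """Nodes connected to every data type other than their own."""
    types = {d.get("data_type") for _, d in g.nodes(data=True)}
    if len(types) < 2:
        raise ValueError("hub detection needs at least 2 data types")
    hubs: set[str] = set()
    coverage: dict[str, set[str]] = {}
    for node, d in g.nodes(data=True):
        own = d.get("data_type")
        seen = {g.nodes[n].get("data_type") for n in g.neighbors(node)}
        coverage[node] = seen
        if seen >= (types - {own}):
            hubs.add(node)
    return HubSet(hubs=hubs, coverage=coverage)
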