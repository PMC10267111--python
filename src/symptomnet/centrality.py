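"""Node importance and focal-node views of a weighted symptom network.

Conventions follow the psychometric-network literature: expected influence
(EI) is the signed sum of a node's edge weights (one-step), strength the
absolute sum; bridge expected influence restricts the sum to edges leaving
the node's own community. Shortest-path measures use the distance transform
``d_ij = 1 / |w_ij|`` on non-zero edges, with fractional credit split across
tied shortest paths; disconnected pairs contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ggm import WeightedNetwork

__all__ = [
    "expected_influence",
    "strength",
    "bridge_expected_influence",
    "betweenness",
    "predictive_betweenness",
    "centrality_table",
    "flow_edges",
    "strongest_edges",
    "FlowView",
]


def expected_influence(net: WeightedNetwork) -> pd.Series:
    """One-step expected influence: signed row sum of edge weights."""
    return pd.Series(net.weights.sum(axis=1), index=net.nodes, name="expected_influence")


def strength(net: WeightedNetwork) -> pd.Series:
    """Node strength: absolute row sum of edge weights."""
    return pd.Series(np.abs(net.weights).sum(axis=1), index=net.nodes, name="strength")


def bridge_expected_influence(net: WeightedNetwork,
                              communities: dict[str, str] | None = None) -> pd.Series:
    """Signed sum of each node's edge weights into *other* communities."""
    communities = communities if communities is not None else net.communities
    missing = [v for v in net.nodes if v not in communities or communities[v] is None]
    if missing:
        raise ValueError(f"nodes without a community label: {missing}")
    labels = np.array([communities[v] for v in net.nodes], dtype=object)
    cross = labels[:, None] != labels[None, :]
    return pd.Series((net.weights * cross).sum(axis=1), index=net.nodes,
                     name="bridge_expected_influence")


def betweenness(net: WeightedNetwork) -> pd.Series:
    """Shortest-path betweenness on distances ``1/|w|``.

    For each node, the number of unordered pairs of other nodes whose
    shortest path passes through it, with ties split fractionally across
    equal-length paths.
    """
    if net.p < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    g = net.to_graph()
    bc = nx.betweenness_centrality(g, normalized=False, weight="distance")
    return pd.Series({v: bc[v] for v in net.nodes}, name="betweenness")


def predictive_betweenness(net: WeightedNetwork, focal: str) -> pd.Series:
    """Focal-anchored betweenness: for each non-focal node v, the (fractional)
    number of shortest paths from the focal node to every other node that
    pass through v. The focal node itself scores NaN."""
    net.index(focal)  # raises KeyError if missing
    g = net.to_graph()
    counts = {v: 0.0 for v in net.nodes}
    for target in net.nodes:
        if target == focal or not nx.has_path(g, focal, target):
            continue
        paths = list(nx.all_shortest_paths(g, focal, target, weight="distance"))
        credit = 1.0 / len(paths)
        for path in paths:
            for v in path[1:-1]:
                counts[v] += credit
    counts[focal] = np.nan
    return pd.Series(counts, name="predictive_betweenness").reindex(net.nodes)


def centrality_table(net: WeightedNetwork, focal: str | None = None) -> pd.DataFrame:
    """Per-node centrality table: raw indices plus z-scored columns.

    Bridge expected influence is included when community labels are present;
    focal-anchored predictive betweenness when ``focal`` is given.
    """
    cols = [strength(net), expected_influence(net)]
    if net.p >= 3:
        cols.append(betweenness(net))
    if net.communities and all(v in net.communities for v in net.nodes):
        cols.append(bridge_expected_influence(net))
    if focal is not None:
        cols.append(predictive_betweenness(net, focal))
    table = pd.concat(cols, axis=1)
    for col in list(table.columns):
        sd = table[col].std(ddof=0)
        z = (table[col] - table[col].mean()) / sd if sd > 0 else table[col] * 0.0
        table[f"z_{col}"] = z
    if net.communities:
        table.insert(0, "community", [net.communities.get(v) for v in net.nodes])
    return table


@dataclass(frozen=True)
class FlowView:
    """Direct neighbourhood of a focal node, as drawn by a flow diagram:
    signed direct edges (sorted by absolute weight), the nodes connected to
    the focal node only through intermediaries, and unreachable nodes."""

    focal: str
    direct: list[tuple[str, float]]
    indirect: list[str]
    unreachable: list[str]


def flow_edges(net: WeightedNetwork, focal: str) -> FlowView:
    """Focal-node flow view: direct edges by |weight| descending (name as
    tie-break), plus indirectly reachable and unreachable node sets."""
    i = net.index(focal)
    direct = [
        (net.nodes[j], float(net.weights[i, j]))
        for j in range(net.p)
        if j != i and net.weights[i, j] != 0.0
    ]
    direct.sort(key=lambda e: (-abs(e[1]), e[0]))
    direct_names = {v for v, _ in direct}
    g = net.to_graph()
    reachable = nx.node_connected_component(g, focal)
    indirect = sorted(reachable - direct_names - {focal})
    unreachable = sorted(set(net.nodes) - reachable - direct_names)
    return FlowView(focal=focal, direct=direct, indirect=indirect, unreachable=unreachable)


def strongest_edges(net: WeightedNetwork, k: int) -> list[tuple[str, str, float]]:
    """Top-k edges by absolute weight; ties broken by the lexicographically
    smaller (node_i, node_j) pair. k beyond the edge count returns all."""
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = [(min(a, b), max(a, b), w) for a, b, w in net.edge_list()]
    edges.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return edges[:k]
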