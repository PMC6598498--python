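"""Node and edge centralities on weighted undirected correlation networks.

Five node measures (degree/strength, eigenvector, closeness, betweenness,
local clustering coefficient) and one edge measure (edge betweenness).
Shortest-path measures use the distance d = 1/w, so a stronger association
means a shorter path; unweighted graphs (w = 1) keep unit distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import CorrelationNetwork

NODE_MEASURES = ("degree", "eigenvector", "closeness", "betweenness", "clustering")
EDGE_MEASURES = ("edge_betweenness",)
MEASURES = NODE_MEASURES + EDGE_MEASURES


@dataclass
class CentralityVector:
    """One centrality value per node (or per edge, for edge measures)."""

    measure: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("one value per name is required")


def _distance_graph(network: CorrelationNetwork) -> nx.Graph:
    """networkx graph with 'weight' and 'distance' (= 1/weight) attributes."""
    G = nx.Graph()
    G.add_nodes_from(range(network.n_nodes))
    A = network.adjacency
    for i, j in network.edges():
        w = float(A[i, j])
        G.add_edge(i, j, weight=w, distance=1.0 / w)
    return G


def degree_centrality(network: CorrelationNetwork) -> CentralityVector:
    """Strength: sum of incident edge weights (edge count when unweighted)."""
    return CentralityVector(
        measure="degree",
        names=list(network.node_names),
        values=network.adjacency.sum(axis=0),
    )


def eigenvector_centrality(
    network: CorrelationNetwork, tol: float = 1e-13, max_iter: int = 10000
) -> CentralityVector:
    """Principal-eigenvector centrality, normalized so the maximum is 1.

    Computed by power iteration on (I + A) from a uniform start, which
    converges on bipartite graphs and gives the symmetric limit when several
    components tie for the spectral radius.  An empty graph returns zeros.
    """
    A = network.adjacency
    n = network.n_nodes
    if A.sum() == 0:
        values = np.zeros(n)
    else:
        x = np.ones(n) / np.sqrt(n)
        for _ in range(max_iter):
            x_new = x + A @ x
            x_new /= np.linalg.norm(x_new)
            if np.linalg.norm(x_new - x) < tol:
                x = x_new
                break
            x = x_new
        x = np.clip(x, 0.0, None)
        values = x / x.max()
    return CentralityVector(
        measure="eigenvector", names=list(network.node_names), values=values
    )


def closeness_centrality(network: CorrelationNetwork) -> CentralityVector:
    """Reachable-only closeness: (#reachable others) / (sum of distances).

    Thresholded correlation networks are frequently disconnected; restricting
    to reachable nodes keeps the measure defined, and isolated nodes get 0.
    """
    G = _distance_graph(network)
    values = np.zeros(network.n_nodes)
    for v in G.nodes:
        lengths = nx.single_source_dijkstra_path_length(G, v, weight="distance")
        total = sum(d for u, d in lengths.items() if u != v)
        reachable = len(lengths) - 1
        values[v] = reachable / total if reachable > 0 else 0.0
    return CentralityVector(
        measure="closeness", names=list(network.node_names), values=values
    )


def betweenness_centrality(network: CorrelationNetwork) -> CentralityVector:
    """Shortest-path betweenness (endpoints excluded, co-minimal paths split)."""
    G = _distance_graph(network)
    bc = nx.betweenness_centrality(G, normalized=False, weight="distance")
    values = np.array([bc[v] for v in range(network.n_nodes)])
    return CentralityVector(
        measure="betweenness", names=list(network.node_names), values=values
    )


def clustering_coefficient(network: CorrelationNetwork) -> CentralityVector:
    """Local clustering coefficient; Barrat generalization for weights.

    c_i = 1 / (s_i (k_i - 1)) * sum over adjacent neighbor pairs (j, h) of
    (w_ij + w_ih) / 2, summed over ordered pairs (equivalently w_ij + w_ih
    over unordered pairs), where s_i is strength and k_i the edge count.
    Reduces to the triangle-count coefficient on unweighted graphs; nodes
    with fewer than 2 neighbors get 0.
    """
    A = network.adjacency
    B = A > 0
    k = B.sum(axis=0)
    s = A.sum(axis=0)
    values = np.zeros(network.n_nodes)
    for i in range(network.n_nodes):
        if k[i] < 2:
            continue
        nbrs = np.flatnonzero(B[i])
        total = 0.0
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                j, h = nbrs[a], nbrs[b]
                if B[j, h]:
                    total += A[i, j] + A[i, h]
        values[i] = total / (s[i] * (k[i] - 1))
    return CentralityVector(
        measure="clustering", names=list(network.node_names), values=values
    )


def edge_name(network_or_names, i: int, j: int) -> str:
    names = (
        network_or_names.node_names
        if isinstance(network_or_names, CorrelationNetwork)
        else network_or_names
    )
    return f"{names[i]}--{names[j]}"


def edge_union(networks) -> list[tuple[int, int]]:
    """Sorted union of edge index pairs (i < j) across networks."""
    pairs: set[tuple[int, int]] = set()
    for net in networks:
        pairs.update(net.edges())
    return sorted(pairs)


def edge_betweenness(
    network: CorrelationNetwork, universe: list[tuple[int, int]] | None = None
) -> CentralityVector:
    """Per-edge shortest-path betweenness over a common edge universe.

    Edges in the universe but absent from this network get 0, so vectors
    stay comparable across groups.
    """
    if universe is None:
        universe = network.edges()
    G = _distance_graph(network)
    eb = nx.edge_betweenness_centrality(G, normalized=False, weight="distance")
    lookup = {}
    for (u, v), val in eb.items():
        lookup[(min(u, v), max(u, v))] = val
    values = np.array([lookup.get(pair, 0.0) for pair in universe])
    names = [edge_name(network, i, j) for i, j in universe]
    return CentralityVector(measure="edge_betweenness", names=names, values=values)


_NODE_FUNCS = {
    "degree": degree_centrality,
    "eigenvector": eigenvector_centrality,
    "closeness": closeness_centrality,
    "betweenness": betweenness_centrality,
    "clustering": clustering_coefficient,
}


def centrality_vector(
    network: CorrelationNetwork,
    measure: str,
    edge_universe: list[tuple[int, int]] | None = None,
) -> CentralityVector:
    """Dispatch to one of the six centrality measures."""
    if measure in _NODE_FUNCS:
        return _NODE_FUNCS[measure](network)
    if measure == "edge_betweenness":
        return edge_betweenness(network, universe=edge_universe)
    raise ValueError(f"unknown centrality measure {measure!r}; choose from {MEASURES}")
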