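"""Network topology metrics and the random-reference comparison protocol.

Association networks are summarized by six statistics — node count, edge
count, average degree, average (unweighted) clustering coefficient, the
fitted degree-distribution power-law exponent, and modularity of the
selected community structure — and compared against uniform G(n, m) random
graphs with the same node and edge counts.  Real co-occurrence networks
cluster far more than their random references; that excess is the
signature of nonrandom community organization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .mi_network import AssociationNetwork
from .snmf import CommunityModel, fuzzy_modularity

__all__ = [
    "TopologyReport",
    "average_degree",
    "average_clustering",
    "power_law_exponent",
    "random_reference",
    "report",
]


@dataclass
class TopologyReport:
    """The six summary statistics of a network + community model."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_clustering: float
    power_law_exponent: float
    modularity: float

    def to_dict(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "avg_clustering": self.avg_clustering,
            "power_law_exponent": self.power_law_exponent,
            "modularity": self.modularity,
        }


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Mean degree 2·E/N of an undirected graph."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if n_edges < 0:
        raise ValueError("n_edges must be >= 0")
    return 2.0 * n_edges / n_nodes


def _binarized_graph(net: AssociationNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    iu, ju = np.nonzero(np.triu(net.A, k=1) > 0)
    g.add_edges_from((net.nodes[i], net.nodes[j]) for i, j in zip(iu, ju))
    return g


def average_clustering(net: AssociationNetwork) -> float:
    """Mean local clustering coefficient over all nodes (weights binarized).

    Nodes of degree < 2 contribute 0, the usual convention.
    """
    g = _binarized_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return float(nx.average_clustering(g, count_zeros=True))


def power_law_exponent(
    net: AssociationNetwork, method: str = "ls"
) -> float:
    """Exponent γ of a power-law fit to the degree distribution.

    ``ls`` (default): magnitude of the least-squares slope of
    log(frequency) against log(degree) over positive-degree,
    positive-frequency bins — the classic log-log regression estimate.
    ``mle``: the continuous maximum-likelihood (Hill/Clauset-style)
    estimate ``1 + n / sum(log(k / (k_min - 0.5)))``.

    Requires at least two distinct positive degrees.
    """
    deg = (net.A > 0).sum(axis=1)
    deg = deg[deg > 0]
    values, freqs = np.unique(deg, return_counts=True)
    if values.size < 2:
        raise ValueError(
            "degenerate degree sequence: need >= 2 distinct positive degrees"
        )
    if method == "ls":
        slope = np.polyfit(np.log(values), np.log(freqs), 1)[0]
        return float(abs(slope))
    if method == "mle":
        kmin = float(values.min())
        return float(1.0 + deg.size / np.log(deg / (kmin - 0.5)).sum())
    raise ValueError(f"unknown method {method!r}")


def random_reference(
    n_nodes: int, n_edges: int, seed: int = 0
) -> AssociationNetwork:
    """Uniform G(n, m) random graph with unit edge weights.

    The null model for topology comparison: identical node and edge
    counts, all structure destroyed.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(
            f"n_edges must be in [0, {max_edges}] for {n_nodes} nodes"
        )
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    A = np.zeros((n_nodes, n_nodes))
    for a, b in g.edges():
        A[a, b] = A[b, a] = 1.0
    return AssociationNetwork(
        nodes=[f"n{i}" for i in range(n_nodes)],
        types=["OTU"] * n_nodes,
        A=A,
    )


def report(
    net: AssociationNetwork, community_model: CommunityModel
) -> TopologyReport:
    """Assemble the six-statistic topology report for a network.

    The modularity row is the fuzzy modularity of the supplied community
    model's memberships.  The power-law exponent is NaN when the degree
    sequence is degenerate (e.g. a regular graph).
    """
    n, e = net.n, net.l
    try:
        gamma = power_law_exponent(net)
    except ValueError:
        gamma = math.nan
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        avg_degree=average_degree(n, e),
        avg_clustering=average_clustering(net),
        power_law_exponent=gamma,
        modularity=fuzzy_modularity(net, community_model.U),
    )
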