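"""Substrate-product network construction.

A reaction set is reduced to an undirected simple graph on metabolites:
for every reaction, each substrate is linked to each product (never
substrate-substrate or product-product), self-pairs are skipped, and
repeated metabolites/edges across reactions are dismissed. The graph
realizes the N x N adjacency matrix A with a_ij = 1 iff metabolites i and
j are linked; reversibility carries no information in this model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from metacore.reactions import Reaction

logger = logging.getLogger(__name__)


def build_network(reactions: Sequence[Reaction], species: str) -> nx.Graph:
    """Build the undirected substrate-product metabolite network.

    Nodes are the union of all substrates and products; every reaction
    contributes the edge {s, p} for each substrate s and product p with
    s != p. The result is independent of reaction order. An empty reaction
    list yields an empty network with a logged warning.
    """
    G = nx.Graph(species=species)
    if not reactions:
        logger.warning("species %s: empty reaction list, empty network", species)
        return G
    for rxn in reactions:
        G.add_nodes_from(rxn.substrates)
        G.add_nodes_from(rxn.products)
        G.add_edges_from(
            (s, p) for s in rxn.substrates for p in rxn.products if s != p
        )
    return G


@dataclass(frozen=True)
class NetworkSummary:
    """Basic topological properties of one metabolite network."""

    species: str
    n_nodes: int
    n_edges: int
    min_degree: int
    max_degree: int
    mean_degree: float
    n_isolated: int


def network_summary(network: nx.Graph) -> NetworkSummary:
    """Summarize node/edge counts and the degree distribution envelope."""
    degrees = [d for _, d in network.degree()]
    n = len(degrees)
    return NetworkSummary(
        species=network.graph.get("species", ""),
        n_nodes=n,
        n_edges=network.number_of_edges(),
        min_degree=min(degrees) if degrees else 0,
        max_degree=max(degrees) if degrees else 0,
        mean_degree=(sum(degrees) / n) if n else 0.0,
        n_isolated=sum(1 for d in degrees if d == 0),
    )
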