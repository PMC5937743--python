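"""k-core decomposition (graph percolation into nested cores).

The k-core of a graph is the maximal subgraph in which every node has
degree >= k inside the subgraph; it is obtained by recursively removing
all nodes of degree < k until none remain. A node's shell (layer) index is
the largest k for which it belongs to the k-core, so the k-shells G_k
partition the node set and cores are nested: core(k+1) is a subset of
core(k). The highest k with a non-empty core is k_max and its core is the
network's central (maximum) core.

The decomposition here is the linear-time bin/bucket peeling scheme of
Batagelj and Zaversnik: sort nodes by degree, repeatedly peel the current
minimum-degree node and decrement its remaining neighbours. Peeling order
among ties is arbitrary; the shell indices are order-independent. A naive
fixpoint implementation (:func:`core_oracle`) is kept as an independent
oracle for testing, never as the production path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass(frozen=True)
class CoreDecomposition:
    """Shell index per metabolite plus the maximum core depth k_max.

    ``shell_index`` maps every node of the decomposed network to the
    largest k such that the node is in the k-core; isolated nodes get
    shell 0. Cores and shells are derived views over this map.
    """

    shell_index: dict[str, int]
    k_max: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.shell_index:
            raise ValueError("decomposition of an empty network")
        object.__setattr__(self, "k_max", max(self.shell_index.values()))


def decompose(network: nx.Graph) -> CoreDecomposition:
    """Compute the full k-core decomposition of an undirected simple graph.

    Returns the shell index of every node; deterministic and independent
    of node iteration order. Raises ``ValueError`` on an empty network.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot decompose an empty network")
    if any(True for _ in nx.selfloop_edges(network)):
        raise ValueError("network must be simple (self-loop found)")

    degree = dict(network.degree())
    # bin sort by degree (Batagelj-Zaversnik)
    nodes = sorted(degree, key=degree.get)
    pos = {v: i for i, v in enumerate(nodes)}
    max_deg = degree[nodes[-1]]
    bin_start = [0] * (max_deg + 2)
    for v in nodes:
        bin_start[degree[v] + 1] += 1
    for d in range(1, max_deg + 2):
        bin_start[d] += bin_start[d - 1]

    shell = dict(degree)  # current degrees become shell indices as peeled
    neighbours = {v: list(network.adj[v]) for v in nodes}
    for i, v in enumerate(nodes):
        for u in neighbours[v]:
            if shell[u] > shell[v]:
                # swap u with the first node of its degree bin, then shrink
                du = shell[u]
                pu, pw = pos[u], bin_start[du]
                w = nodes[pw]
                if u != w:
                    nodes[pu], nodes[pw] = w, u
                    pos[u], pos[w] = pw, pu
                bin_start[du] += 1
                shell[u] -= 1
    return CoreDecomposition(shell_index=shell)


def core(decomp: CoreDecomposition, k: int) -> set[str]:
    """Nodes of the k-core: every node with shell index >= k.

    The paper-style cumulative "layer k" is exactly this set. Raises
    ``ValueError`` if k is outside 1..k_max.
    """
    if not 1 <= k <= decomp.k_max:
        raise ValueError(f"k={k} out of range 1..{decomp.k_max}")
    return {v for v, s in decomp.shell_index.items() if s >= k}


def shell(decomp: CoreDecomposition, k: int) -> set[str]:
    """Nodes with shell index exactly k (the k-shell G_k); over all k
    these partition the node set. Raises ``ValueError`` outside 0..k_max."""
    if not 0 <= k <= decomp.k_max:
        raise ValueError(f"k={k} out of range 0..{decomp.k_max}")
    return {v for v, s in decomp.shell_index.items() if s == k}


def max_core(decomp: CoreDecomposition) -> set[str]:
    """The maximum (central) core: core(k_max)."""
    return core(decomp, decomp.k_max)


def core_oracle(network: nx.Graph, k: int) -> set[str]:
    """Naive fixpoint k-core: repeatedly delete every node of current
    degree < k until none remains; returns the survivors (possibly empty).

    Independent test oracle for :func:`decompose`; quadratic, not for
    production use.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    H = network.copy()
    while True:
        doomed = [v for v, d in H.degree() if d < k]
        if not doomed:
            return set(H.nodes)
        H.remove_nodes_from(doomed)
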