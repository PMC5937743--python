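"""GML read/write for metabolite networks.

The on-disk dialect is the one the field's network suites exchange:
numeric node ``id``, quoted string ``label`` holding the metabolite name,
``directed 0``. Reading is lenient (directed input is flattened, duplicate
edges and self-loops are dropped with a warning); writing is normalized.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)


def read_gml(path: str | Path, species: str | None = None) -> nx.Graph:
    """Read an undirected metabolite network from GML.

    Node ``label`` attributes become metabolite names (the node keys of the
    returned graph). Directed input is flattened to undirected; self-loops
    and duplicate edges are dropped with a logged warning. Isolated nodes
    are retained.

    Parameters
    ----------
    path
        GML file with ``id`` and ``label`` node attributes.
    species
        Species label stored in ``G.graph["species"]``; defaults to the
        file stem.

    Raises
    ------
    networkx.NetworkXError
        On malformed GML or a node without a label.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    # parse in multigraph mode so duplicate edges are tolerated, then collapse
    if "multigraph" not in text:
        text = text.replace("graph [", "graph [\n  multigraph 1", 1)
    G = nx.parse_gml(text, label="label")
    if G.is_directed():
        logger.warning("%s: directed GML flattened to undirected", path)
        G = G.to_undirected()
    if G.is_multigraph():
        simple = nx.Graph()
        simple.add_nodes_from(G.nodes)
        dupes = 0
        for u, v in G.edges():
            if simple.has_edge(u, v):
                dupes += 1
            simple.add_edge(u, v)
        if dupes:
            logger.warning("%s: dropped %d duplicate edge(s)", path, dupes)
        G = simple
    loops = list(nx.selfloop_edges(G))
    if loops:
        logger.warning("%s: dropped %d self-loop(s)", path, len(loops))
        G.remove_edges_from(loops)
    G.graph["species"] = species if species is not None else path.stem
    return G


def write_gml(network: nx.Graph, path: str | Path) -> None:
    """Write a metabolite network as undirected GML with numeric node ids
    and metabolite names as quoted ``label`` attributes.

    ``read_gml(write_gml(G))`` reproduces the node-label set and edge set.
    """
    path = Path(path)
    # strip node/edge data: the exchange format carries topology + labels only
    clean = nx.Graph()
    clean.add_nodes_from(network.nodes)
    clean.add_edges_from(network.edges)
    nx.write_gml(clean, path)
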