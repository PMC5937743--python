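"""Distribution of metabolite sets over the percolation layers.

"Layer k" is read cumulatively as the k-core (the full content of each
kcore), so a layer profile reports, for every k from 1 to k_max, the size
of the k-core, the size of the exclusive k-shell, and how much of the core
a target metabolite set (common metabolites, curated secondary lists, ...)
accounts for. Cross-species composition of the maximum cores is exposed as
a boolean presence matrix, and reaction-level integration as the fraction
of reactions touching an anchor set (typically the maximum core).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from metacore.kcore import CoreDecomposition, decompose, max_core
from metacore.reactions import Reaction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LayerProfile:
    """Per-layer counts and target fractions for one network.

    ``table`` has one row per k in 1..k_max with columns ``k``,
    ``core_size``, ``shell_size``, ``target_in_core`` and ``fraction``
    (= target_in_core / core_size). ``n_absent`` counts target names not
    present anywhere in the network.
    """

    target_label: str
    table: pd.DataFrame
    n_absent: int

    def fraction_at(self, k: int) -> float:
        row = self.table.loc[self.table["k"] == k, "fraction"]
        if row.empty:
            raise ValueError(f"k={k} not in profile")
        return float(row.iloc[0])


def layer_profile(
    decomp: CoreDecomposition,
    target: set[str],
    label: str = "target",
) -> LayerProfile:
    """Profile a target metabolite set across the cumulative cores.

    The target may contain names absent from the network (curated lists
    do); absentees count as not-in-core at every k and are tallied in
    ``n_absent`` with a logged message.
    """
    shell_index = decomp.shell_index
    n_absent = sum(1 for m in target if m not in shell_index)
    if n_absent:
        logger.info(
            "target %s: %d of %d member(s) absent from the network",
            label, n_absent, len(target),
        )
    rows = []
    for k in range(1, decomp.k_max + 1):
        core_k = [v for v, s in shell_index.items() if s >= k]
        in_core = sum(1 for v in core_k if v in target)
        shell_size = sum(1 for s in shell_index.values() if s == k)
        rows.append(
            {
                "k": k,
                "core_size": len(core_k),
                "shell_size": shell_size,
                "target_in_core": in_core,
                "fraction": in_core / len(core_k),
            }
        )
    return LayerProfile(target_label=label, table=pd.DataFrame(rows), n_absent=n_absent)


def common_metabolites(networks: Sequence[nx.Graph]) -> set[str]:
    """Intersection of the metabolite sets of all given networks."""
    if not networks:
        raise ValueError("need at least one network")
    common = set(networks[0].nodes)
    for G in networks[1:]:
        common &= set(G.nodes)
    return common


def noncommon_metabolites(
    network: nx.Graph, all_networks: Sequence[nx.Graph]
) -> set[str]:
    """One species' metabolites outside the all-species intersection.

    Together with the common set this partitions the species' node set, so
    common and non-common core fractions sum to one at every layer.
    """
    return set(network.nodes) - common_metabolites(all_networks)


@dataclass(frozen=True)
class PresenceMatrix:
    """Maximum-core membership across species.

    ``table``: boolean DataFrame, rows = metabolites (lexicographic),
    columns = species labels, True where the metabolite is in that
    species' maximum core. ``intersection``: metabolites present in every
    species' maximum core.
    """

    table: pd.DataFrame
    intersection: set[str]


def max_core_presence(
    networks: Sequence[nx.Graph],
    decompositions: Sequence[CoreDecomposition] | None = None,
) -> PresenceMatrix:
    """Tabulate which metabolites occupy each species' maximum core.

    Decompositions are computed on the fly unless supplied (one per
    network, same order). Rows are the union of all maximum cores, sorted;
    every row is present in at least one species by construction.
    """
    if not networks:
        raise ValueError("need at least one network")
    if decompositions is None:
        decompositions = [decompose(G) for G in networks]
    species = [G.graph.get("species", f"species_{i}") for i, G in enumerate(networks)]
    cores = [max_core(d) for d in decompositions]
    union = sorted(set().union(*cores), key=str)
    data = {sp: [m in c for m in union] for sp, c in zip(species, cores)}
    table = pd.DataFrame(data, index=union)
    intersection = set(union)
    for c in cores:
        intersection &= c
    return PresenceMatrix(table=table, intersection=intersection)


@dataclass(frozen=True)
class ReactionCoverage:
    """How many reactions contain at least one anchor metabolite."""

    n_hit: int
    n_miss: int

    @property
    def n_total(self) -> int:
        return self.n_hit + self.n_miss

    @property
    def fraction(self) -> float:
        return self.n_hit / self.n_total


def reaction_coverage(
    reactions: Sequence[Reaction], anchor: Iterable[str]
) -> ReactionCoverage:
    """Fraction of reactions whose metabolites intersect the anchor set
    (typically a maximum core). Raises ``ValueError`` on an empty
    reaction list; an empty anchor gives coverage 0."""
    if not reactions:
        raise ValueError("empty reaction list")
    anchor = set(anchor)
    n_hit = sum(1 for r in reactions if r.metabolites & anchor)
    return ReactionCoverage(n_hit=n_hit, n_miss=len(reactions) - n_hit)
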