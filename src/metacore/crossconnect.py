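"""Cross-connection of metabolic classes (modules).

Metabolites are assigned one class each from user-supplied lists (amino
acids, nucleotides, lipids, carbohydrates, ...). Members of the maximum
core are pulled out of their base class into the reserved "max_core"
class to avoid ambiguity; nodes on no list become "unclassified". The
cross-connection matrix then counts network links between class pairs:
each undirected edge increments exactly one unordered class-pair cell
(within-class edges land on the diagonal once), so diagonal plus upper
triangle always sums to the network's edge count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from metacore.reactions import MetaboliteList

logger = logging.getLogger(__name__)

MAX_CORE_LABEL = "max_core"
UNCLASSIFIED_LABEL = "unclassified"
RESERVED_LABELS = frozenset({MAX_CORE_LABEL, UNCLASSIFIED_LABEL})


class ReservedLabelError(ValueError):
    """A base class list uses a reserved label."""


@dataclass(frozen=True)
class ClassAssignment:
    """Single class label per network node, max-core precedence applied.

    ``classes`` is the ordered label list: "max_core" first, then the base
    classes in input order, then "unclassified".
    """

    class_of: dict[str, str]
    classes: tuple[str, ...]


def assign_classes(
    base_classes: Sequence[MetaboliteList],
    max_core_set: set[str],
    network: nx.Graph,
) -> ClassAssignment:
    """Assign every network node exactly one class label.

    Precedence: maximum-core members get "max_core" regardless of base
    membership; remaining nodes get their base class; nodes on two or more
    base lists get the first-listed class with a logged warning; nodes on
    no list get "unclassified".

    Raises
    ------
    ReservedLabelError
        If a base class is labelled "max_core" or "unclassified".
    """
    labels = [bl.label for bl in base_classes]
    bad = RESERVED_LABELS.intersection(labels)
    if bad:
        raise ReservedLabelError(f"reserved class label(s) used: {sorted(bad)}")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate base class labels in {labels}")

    class_of: dict[str, str] = {}
    n_overlap = 0
    for node in network.nodes:
        if node in max_core_set:
            class_of[node] = MAX_CORE_LABEL
            continue
        hits = [bl.label for bl in base_classes if node in bl.members]
        if len(hits) > 1:
            n_overlap += 1
            logger.warning(
                "metabolite %r in classes %s; assigned first-listed %r",
                node, hits, hits[0],
            )
        class_of[node] = hits[0] if hits else UNCLASSIFIED_LABEL
    if n_overlap:
        logger.warning("%d metabolite(s) were on multiple base lists", n_overlap)
    return ClassAssignment(
        class_of=class_of,
        classes=(MAX_CORE_LABEL, *labels, UNCLASSIFIED_LABEL),
    )


@dataclass(frozen=True)
class CrossConnectionMatrix:
    """Class-pair link counts plus per-class node counts and proportions.

    ``counts`` is square and symmetric over the assignment's class order;
    off-diagonal cells are mirrored for row-wise reading, within-class
    counts sit on the diagonal once, so diagonal + upper triangle = |E|.
    """

    counts: pd.DataFrame
    node_counts: pd.Series
    node_proportions: pd.Series


def cross_connection_counts(
    network: nx.Graph, assignment: ClassAssignment
) -> CrossConnectionMatrix:
    """Count links between metabolic classes.

    Each undirected edge {u, v} increments M[c(u)][c(v)] once (and the
    symmetric twin when the classes differ). Raises ``KeyError`` if a
    network node is missing from the assignment.
    """
    classes = list(assignment.classes)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    class_of = assignment.class_of
    missing = [v for v in network.nodes if v not in class_of]
    if missing:
        raise KeyError(f"{len(missing)} node(s) missing from assignment: "
                       f"{sorted(missing)[:5]}...")
    for u, v in network.edges:
        cu, cv = class_of[u], class_of[v]
        counts.loc[cu, cv] += 1
        if cu != cv:
            counts.loc[cv, cu] += 1
    node_counts = pd.Series(0, index=classes, dtype=int)
    for v in network.nodes:
        node_counts[class_of[v]] += 1
    n = max(node_counts.sum(), 1)
    return CrossConnectionMatrix(
        counts=counts,
        node_counts=node_counts,
        node_proportions=node_counts / n,
    )
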