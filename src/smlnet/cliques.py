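"""LLN modules by k-clique percolation and their interface lncRNAs.

A module is a union of k-cliques chained through (k-1)-node overlaps
(clique percolation); lncRNAs belonging to more than one module sit at the
interface of communities and are treated as functionally central.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
from networkx.algorithms.community import k_clique_communities as _nx_cpm


@dataclass
class KCliqueCommunitySet:
    """Communities of one graph at a fixed k.

    ``communities`` are sorted node tuples in deterministic order;
    ``clique_count`` is the number of maximal cliques of size >= k that seed
    the percolation.
    """

    k: int
    communities: list[tuple[str, ...]]
    clique_count: int


@dataclass
class InterfaceReport:
    """Nodes shared by >= 2 communities with their membership map."""

    interface_nodes: set[str]
    memberships: dict[str, set[int]]
    majority_atc: dict[str, str] = field(default_factory=dict)


def _check_simple(graph: nx.Graph) -> None:
    if any(u == v for u, v in graph.edges()):
        raise ValueError("graph must not contain self-loops")


def maximal_cliques(graph: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques (Bron-Kerbosch with pivoting), sorted."""
    _check_simple(graph)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    return sorted(cliques)


def k_clique_communities(graph: nx.Graph, k: int) -> KCliqueCommunitySet:
    """Clique-percolation communities: unions of adjacent k-cliques.

    Two k-cliques are adjacent iff they share k-1 nodes.  k-cliques are
    reached through the maximal cliques of size >= k (two maximal cliques
    sharing >= k-1 nodes percolate, and all k-cliques within one maximal
    clique pairwise share k-1 nodes), which is the standard acceleration.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    _check_simple(graph)
    cliques = [c for c in nx.find_cliques(graph) if len(c) >= k]
    communities = sorted(
        tuple(sorted(c)) for c in _nx_cpm(graph, k, cliques=cliques)
    )
    return KCliqueCommunitySet(k=k, communities=communities, clique_count=len(cliques))


def interface_nodes(community_set: KCliqueCommunitySet) -> InterfaceReport:
    """Nodes that belong to two or more communities."""
    memberships: dict[str, set[int]] = {}
    for i, comm in enumerate(community_set.communities):
        for node in comm:
            memberships.setdefault(node, set()).add(i)
    interface = {n for n, m in memberships.items() if len(m) >= 2}
    return InterfaceReport(interface_nodes=interface, memberships=memberships)


def majority_atc_label(
    lncrna: str, smln: nx.Graph, atc_map: Mapping[str, str]
) -> str:
    """Most frequent ATC class among a lncRNA's drug neighbors in the SMLN.

    Ties are broken lexicographically; neighbors without an ATC label are
    ignored, and having none is an error.
    """
    labels = [atc_map[d] for d in smln.neighbors(lncrna) if d in atc_map]
    if not labels:
        raise ValueError(f"{lncrna!r} has no ATC-labeled drug neighbors")
    counts = Counter(labels)
    top = max(counts.values())
    return min(label for label, c in counts.items() if c == top)


def annotate_interface_atc(
    report: InterfaceReport, smln: nx.Graph, atc_map: Mapping[str, str]
) -> InterfaceReport:
    """Fill ``majority_atc`` for every interface node present in the SMLN."""
    for node in sorted(report.interface_nodes):
        if node in smln:
            report.majority_atc[node] = majority_atc_label(node, smln, atc_map)
    return report
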