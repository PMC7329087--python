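"""Greedy agglomerative modularity communities (Newman's fast algorithm).

The phylogram pipeline annotates each tree with the clusters found by
greedy modularity maximization: starting from singleton communities, merge
the pair with the largest modularity gain and keep the best partition seen.
The Clauset–Newman–Moore implementation in networkx is exactly this
procedure; we wrap it to fix the degenerate cases and return the modularity.
"""

from __future__ import annotations

import networkx as nx
from networkx.algorithms import community as nx_community

from .errors import DataError


def fast_newman(graph: nx.Graph) -> tuple[list[frozenset], float]:
    """Best greedy-merge partition of an undirected graph plus its modularity Q.

    Returns the communities as a list of frozensets sorted by smallest
    member.  Graphs without edges get the all-singletons partition with
    Q = 0 (modularity is undefined there; zero is the neutral convention).
    """
    if graph.number_of_nodes() == 0:
        raise DataError("community detection needs a non-empty graph")
    if graph.number_of_edges() == 0:
        parts = [frozenset([n]) for n in graph.nodes]
    elif graph.number_of_nodes() == 1:
        parts = [frozenset(graph.nodes)]
    else:
        parts = [frozenset(c) for c in
                 nx_community.greedy_modularity_communities(graph)]
    q = nx_community.modularity(graph, parts) if graph.number_of_edges() else 0.0
    parts.sort(key=lambda c: sorted(map(str, c)))
    return parts, float(q)
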