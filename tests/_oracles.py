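"""Independent oracles used by the test suite.

Everything here is deliberately naive — brute-force enumeration or direct
textbook formulas — and never shares code with the implementation paths it
checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from networkx.algorithms import community as nx_community
from scipy.optimize import minimize


def all_partitions(nodes):
    """Every set partition of the nodes (restricted-growth recursion)."""
    nodes = list(nodes)

    def rec(i, parts):
        if i == len(nodes):
            yield [set(p) for p in parts]
            return
        for p in parts:
            p.append(nodes[i])
            yield from rec(i + 1, parts)
            p.pop()
        parts.append([nodes[i]])
        yield from rec(i + 1, parts)
        parts.pop()

    yield from rec(0, [])


def max_modularity_bruteforce(graph: nx.Graph) -> float:
    """Exhaustive maximum modularity over all partitions (<= 8 nodes)."""
    return max(nx_community.modularity(graph, p)
               for p in all_partitions(graph.nodes))


def cox_logpl_newton(X: np.ndarray, durations: np.ndarray,
                     events: np.ndarray) -> float:
    """Textbook Cox log partial likelihood, maximized from scratch.

    Valid for distinct event times (no tie correction needed, so Breslow,
    Efron and the exact likelihood coincide).
    """
    X = np.asarray(X, float)
    n, p = X.shape

    def neg(beta):
        eta = X @ beta
        out = 0.0
        for i in range(n):
            if events[i]:
                risk = durations >= durations[i]
                out -= eta[i] - np.log(np.sum(np.exp(eta[risk])))
        return out

    res = minimize(neg, np.zeros(p), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return float(-res.fun)


def dominance_front_oracle(coords: np.ndarray) -> np.ndarray:
    """All-pairs O(n^2) non-dominance mask over (k, value), both minimized."""
    coords = np.asarray(coords, float)
    n = len(coords)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (coords[j, 0] <= coords[i, 0] and coords[j, 1] <= coords[i, 1]
                    and (coords[j, 0] < coords[i, 0]
                         or coords[j, 1] < coords[i, 1])):
                mask[i] = False
                break
    return mask


def diameter_endpoints_bruteforce(tree_graph: nx.Graph, leaves: dict):
    """All leaf pairs at maximal unweighted distance, as sorted name pairs."""
    best = -1
    pairs = []
    for (na, a), (nb, b) in itertools.combinations(sorted(leaves.items()), 2):
        d = nx.shortest_path_length(tree_graph, a, b)
        if d > best:
            best, pairs = d, []
        if d == best:
            pairs.append(tuple(sorted((na, nb))))
    return best, pairs


def sibling_sets_bruteforce(graph: nx.Graph, nodes: set, root,
                            names: dict) -> dict:
    """Leaf -> sibling leaf set in a clade, by explicit rooted traversal."""
    parent = {root: None}
    order = [root]
    seen = {root}
    while order:
        u = order.pop()
        for v in graph.neighbors(u):
            if v in nodes and v not in seen:
                parent[v] = u
                seen.add(v)
                order.append(v)

    def leaves_below(u, avoid):
        found = set()
        stack = [u]
        visited = {u} | avoid
        while stack:
            w = stack.pop()
            if w in names:
                found.add(names[w])
            for v in graph.neighbors(w):
                if v in nodes and v not in visited:
                    visited.add(v)
                    stack.append(v)
        return found

    out = {}
    for node, name in names.items():
        if node not in nodes:
            continue
        p = parent[node]
        if p is None:
            out[name] = frozenset()
            continue
        avoid = {node}
        if parent[p] is not None:
            avoid.add(parent[p])
        out[name] = frozenset(leaves_below(p, avoid) - {name})
    return out
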