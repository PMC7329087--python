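"""Unrooted phylograms and Saitou–Nei neighbor joining.

A phylogram here is an unrooted tree whose leaves are dataset features,
with non-negative branch lengths.  Downstream clade procedures use edge
counts only, but branch lengths are kept for reporting and for the additive
reconstruction guarantees of neighbor joining.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .distance import DistanceMatrix
from .errors import DataError, NumericError


@dataclass
class Phylogram:
    """Unrooted tree over named leaves, backed by a networkx graph.

    Nodes are integers; leaf nodes carry a ``name`` attribute.  Edge attribute
    ``length`` holds the branch length.  ``communities`` optionally records a
    node partition (clusters) with its modularity.
    """

    graph: nx.Graph
    communities: list[frozenset[int]] | None = None
    modularity: float | None = None
    _leaf_by_name: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not nx.is_tree(self.graph):
            raise DataError("phylogram graph must be a tree")
        self._leaf_by_name = {}
        for node, data in self.graph.nodes(data=True):
            name = data.get("name")
            if name is not None:
                if name in self._leaf_by_name:
                    raise DataError(f"duplicate leaf label {name!r}")
                self._leaf_by_name[name] = node
        if not self._leaf_by_name:
            raise DataError("phylogram has no labeled leaves")

    # -- structure ---------------------------------------------------------
    @property
    def leaf_names(self) -> list[str]:
        return sorted(self._leaf_by_name)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_by_name)

    def leaf_node(self, name: str) -> int:
        try:
            return self._leaf_by_name[name]
        except KeyError:
            raise DataError(f"no leaf named {name!r}") from None

    def node_name(self, node: int) -> str | None:
        return self.graph.nodes[node].get("name")

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the leaf-to-leaf path."""
        return nx.shortest_path_length(self.graph, self.leaf_node(a),
                                       self.leaf_node(b), weight="length")

    def path_length_matrix(self) -> DistanceMatrix:
        names = self.leaf_names
        k = len(names)
        d = np.zeros((k, k))
        for i, j in itertools.combinations(range(k), 2):
            d[i, j] = d[j, i] = self.path_length(names[i], names[j])
        return DistanceMatrix(names, d)

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_edges(cls, edges, leaves: dict[int, str]) -> "Phylogram":
        """Build from (u, v, length) triples and a node->leaf-name map."""
        g = nx.Graph()
        for u, v, length in edges:
            g.add_edge(u, v, length=float(length))
        for node, name in leaves.items():
            g.add_node(node, name=name)
        return cls(g)

    # -- Newick ------------------------------------------------------------
    def to_newick(self) -> str:
        """Canonical Newick string: deterministic rooting and child order.

        Rooted for serialization at the neighbor of the lexicographically
        smallest leaf (at the leaf itself for a 2-leaf tree); children are
        ordered by their smallest descendant leaf name.
        """
        if self.n_leaves == 2:
            a, b = self.leaf_names
            length = self.path_length(a, b)
            return f"({_quote_label(a)}:0,{_quote_label(b)}:{length:.10g});"
        first = self.leaf_node(self.leaf_names[0])
        root = next(iter(self.graph.neighbors(first)))

        def min_leaf(node: int, parent: int | None) -> str:
            name = self.node_name(node)
            if name is not None:
                return name
            return min(min_leaf(c, node) for c in self.graph.neighbors(node)
                       if c != parent)

        def render(node: int, parent: int | None) -> str:
            name = self.node_name(node)
            children = [c for c in self.graph.neighbors(node) if c != parent]
            label = _quote_label(name) if name is not None else ""
            if not children:
                return label
            children.sort(key=lambda c: min_leaf(c, node))
            inner = ",".join(
                f"{render(c, node)}:{self.graph.edges[node, c]['length']:.10g}"
                for c in children)
            return f"({inner}){label}"

        return render(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Phylogram":
        """Parse a Newick string (via scikit-bio) into an unrooted phylogram."""
        import skbio

        tnode = skbio.TreeNode.read(io.StringIO(text))
        g = nx.Graph()
        counter = itertools.count()
        ids: dict[int, int] = {}

        def node_id(sk) -> int:
            key = id(sk)
            if key not in ids:
                ids[key] = next(counter)
                if sk.name is not None:
                    g.add_node(ids[key], name=str(sk.name))
                else:
                    g.add_node(ids[key])
            return ids[key]

        for sk in tnode.traverse():
            if sk.parent is not None:
                length = sk.length if sk.length is not None else 0.0
                g.add_edge(node_id(sk.parent), node_id(sk), length=float(length))
        # collapse a degree-2 serialization root back to an unrooted tree
        rid = node_id(tnode)
        if g.degree(rid) == 2 and g.nodes[rid].get("name") is None:
            a, b = list(g.neighbors(rid))
            length = g.edges[rid, a]["length"] + g.edges[rid, b]["length"]
            g.remove_node(rid)
            g.add_edge(a, b, length=length)
        return cls(g)


def _quote_label(name: str) -> str:
    if any(ch in name for ch in " ()[]':;,"):
        return "'" + name.replace("'", "''") + "'"
    return name


def neighbor_joining(dm: DistanceMatrix) -> Phylogram:
    """Classical Saitou–Nei neighbor joining on a distance matrix.

    Iteratively joins the pair minimizing Q(i,j) = (r-2) d(i,j) - R_i - R_j
    (ties broken by smallest index pair), with the standard branch-length
    formulas.  Negative branch lengths are clamped to zero and the deficit
    moved to the sister branch, preserving the pair's joint length.
    """
    k = len(dm.names)
    if k < 2:
        raise DataError("neighbor joining needs at least 2 leaves")
    if not np.isfinite(dm.d).all():
        raise NumericError("distance matrix has non-finite entries")

    g = nx.Graph()
    active = list(range(k))  # graph node ids of active cluster roots
    for i, name in enumerate(dm.names):
        g.add_node(i, name=name)
    next_id = k
    d = {(min(i, j), max(i, j)): dm.d[i, j]
         for i in range(k) for j in range(i + 1, k)}

    def dist(a: int, b: int) -> float:
        return d[(min(a, b), max(a, b))]

    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ia in range(r):
            for ib in range(ia + 1, r):
                a, b = active[ia], active[ib]
                q = (r - 2) * dist(a, b) - row_sum[a] - row_sum[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        u = next_id
        next_id += 1
        dab = dist(a, b)
        va = 0.5 * dab + (row_sum[a] - row_sum[b]) / (2 * (r - 2))
        vb = dab - va
        va, vb = _clamp_pair(va, vb)
        g.add_edge(a, u, length=va)
        g.add_edge(b, u, length=vb)
        for c in active:
            if c not in (a, b):
                d[(min(c, u), max(c, u))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [u]

    if len(active) == 2:
        a, b = active
        g.add_edge(a, b, length=max(dist(a, b), 0.0))
    else:  # final star join of three clusters
        a, b, c = active
        u = next_id
        va = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
        vb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
        vc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
        for node, v in ((a, va), (b, vb), (c, vc)):
            g.add_edge(node, u, length=max(v, 0.0))
    return Phylogram(g)


def _clamp_pair(va: float, vb: float) -> tuple[float, float]:
    if va < 0:
        vb += va
        va = 0.0
    if vb < 0:
        va += vb
        vb = 0.0
    return max(va, 0.0), max(vb, 0.0)
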