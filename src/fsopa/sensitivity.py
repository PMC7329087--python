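"""Clade-based (SM1) and target-based (SM2) feature sensitivity.

Each best/worst phylogram pair at a pressure category is split into two
clades by cutting the middle edge of its longest (diameter, edge-counted)
path.  Best and worst clades are paired by congruence (shared-leaf count);
SM1 selects the leaves whose sibling sets differ between the paired clades,
SM2 selects, around a target leaf, the target plus the leaves of its
sibling subtree in both clades containing it.  The union over categories
(and targets) gives s_clade, s_criterion and the selected set r.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .errors import DataError
from .model import build_model, model_object_columns
from .sampling import RankedSubsets, SUBSET_LABELS
from .table import FeatureTable
from .tree import Phylogram

CATEGORIES = ("2C", "4C", "8C")


@dataclass(frozen=True)
class Clade:
    """A rooted subtree obtained by cutting one phylogram edge.

    ``root`` is the cut-edge endpoint inside the clade; rooting there is the
    only rooting the cut itself induces, and defines parent/sibling
    relations for the leaves.
    """

    tree: Phylogram
    nodes: frozenset[int]
    root: int
    label: str = ""

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(n for n in (self.tree.node_name(v) for v in self.nodes)
                         if n is not None)

    def _parents(self) -> dict[int, int | None]:
        sub = self.tree.graph.subgraph(self.nodes)
        parents: dict[int, int | None] = {self.root: None}
        for u, v in nx.bfs_edges(sub, self.root):
            parents[v] = u
        return parents

    def sibling_set(self, leaf: str) -> frozenset[str]:
        """Leaf names in the subtree hanging off the other side of the leaf's parent.

        All leaves reachable from the leaf's parent without passing through
        the leaf itself or back toward the root.  Empty for a singleton
        clade or when the leaf sits at the cut point.
        """
        node = self.tree.leaf_node(leaf)
        if node not in self.nodes:
            raise DataError(f"leaf {leaf!r} is not in clade {self.label or '?'}")
        parents = self._parents()
        if parents[node] is None:  # leaf is the cut point
            return frozenset()
        parent = parents[node]
        blocked = {node}
        if parents[parent] is not None:
            blocked.add(parents[parent])
        sub = self.tree.graph.subgraph(self.nodes - blocked)
        names = []
        for reached in nx.node_connected_component(sub, parent):
            name = self.tree.node_name(reached)
            if name is not None:
                names.append(name)
        return frozenset(names)


def longest_path(tree: Phylogram) -> list[int]:
    """A diameter path by edge count, as a node list from start to end leaf.

    Ties are broken by the lexicographically smallest (start, end) leaf-name
    pair with start <= end.
    """
    names = tree.leaf_names
    if len(names) < 2:
        raise DataError("longest path needs at least 2 leaves")
    best: tuple[int, str, str] | None = None
    for a in names:
        lengths = nx.single_source_shortest_path_length(tree.graph,
                                                        tree.leaf_node(a))
        for b in names:
            if a < b:
                key = (-lengths[tree.leaf_node(b)], a, b)
                if best is None or key < best:
                    best = key
    _, a, b = best
    return nx.shortest_path(tree.graph, tree.leaf_node(a), tree.leaf_node(b))


def split_middle(tree: Phylogram) -> list[tuple[Clade, Clade]]:
    """Cut the middle edge of the diameter path into two clades.

    An odd-length path has a unique middle edge; an even-length path yields
    both middle candidates, to be arbitrated downstream by congruence.  In
    each returned pair the first clade contains the path's start leaf.
    """
    path = longest_path(tree)
    m = len(path) - 1  # edge count
    if m % 2 == 1:
        cut_indices = [m // 2]
    else:
        cut_indices = [m // 2 - 1, m // 2]
    out = []
    for idx in cut_indices:
        u, v = path[idx], path[idx + 1]
        g = tree.graph.copy()
        g.remove_edge(u, v)
        side_u = frozenset(nx.node_connected_component(g, u))
        side_v = frozenset(nx.node_connected_component(g, v))
        out.append((Clade(tree, side_u, u, "C1"), Clade(tree, side_v, v, "C2")))
    return out


@dataclass
class CongruentPairing:
    """The congruence-chosen pairing of best and worst clades for one category."""

    p1: tuple[Clade, Clade]
    p2: tuple[Clade, Clade]
    congruence: int
    best_split: tuple[Clade, Clade]
    worst_split: tuple[Clade, Clade]


def _congruence(a: Clade, b: Clade) -> int:
    return len(a.leaves & b.leaves)


def pair_by_congruence(best_splits: Sequence[tuple[Clade, Clade]],
                       worst_splits: Sequence[tuple[Clade, Clade]]) -> CongruentPairing:
    """Choose the split candidates and pairing maximizing p1's congruence.

    Among all candidate split combinations and both pairings, keep the one
    whose most congruent pair has maximal shared-leaf count; ties prefer
    fewer total symmetric-difference leaves, then a lexicographic key that
    is symmetric under a best/worst exchange.
    """
    universe = best_splits[0][0].leaves | best_splits[0][1].leaves
    for c1, c2 in itertools.chain(best_splits, worst_splits):
        if c1.leaves | c2.leaves != universe:
            raise DataError("best and worst splits cover different leaf universes")

    candidates = []
    for bs, ws in itertools.product(best_splits, worst_splits):
        for flip in (False, True):
            w1, w2 = (ws[1], ws[0]) if flip else (ws[0], ws[1])
            pairs = [(bs[0], w1), (bs[1], w2)]
            scored = sorted(
                pairs,
                key=lambda p: (-_congruence(*p),
                               tuple(sorted((tuple(sorted(p[0].leaves)),
                                             tuple(sorted(p[1].leaves)))))))
            p1, p2 = scored
            cong = _congruence(*p1)
            symdiff = sum(len(a.leaves ^ b.leaves) for a, b in pairs)
            lexkey = tuple(sorted((tuple(sorted(p1[0].leaves)),
                                   tuple(sorted(p1[1].leaves)))))
            candidates.append(((-cong, symdiff, lexkey),
                               CongruentPairing(p1, p2, cong, bs, (w1, w2))))
    candidates.sort(key=lambda item: item[0])
    return candidates[0][1]


@dataclass
class SM1CategoryResult:
    category: str
    pairing: CongruentPairing
    s1: frozenset[str]
    s2: frozenset[str]
    unpaired: frozenset[str]

    @property
    def selected(self) -> frozenset[str]:
        return self.s1 | self.s2


def sm1(best: Phylogram, worst: Phylogram, category: str = "") -> SM1CategoryResult:
    """Clade-based sensitivity for one best/worst phylogram pair.

    For each congruence-paired clade pair, every leaf present in both clades
    is selected when its sibling leaf set differs between the two; leaves
    present in only one clade of a pair cannot be compared and are recorded
    as unpaired.
    """
    if set(best.leaf_names) != set(worst.leaf_names):
        raise DataError("best and worst phylograms have different leaf sets")
    pairing = pair_by_congruence(split_middle(best), split_middle(worst))
    results: list[frozenset[str]] = []
    unpaired: set[str] = set()
    for a, b in (pairing.p1, pairing.p2):
        shared = a.leaves & b.leaves
        unpaired |= a.leaves ^ b.leaves
        results.append(frozenset(
            leaf for leaf in shared if a.sibling_set(leaf) != b.sibling_set(leaf)))
    return SM1CategoryResult(category, pairing, results[0], results[1],
                             frozenset(unpaired))


def sm2(pairing: CongruentPairing, target: str) -> frozenset[str]:
    """Target-based sensitivity: the target plus its sibling subtrees.

    Uses the same four clades SM1 found: in the best-model clade and the
    worst-model clade containing the target, select the target together with
    every leaf of the subtree hanging off the target's parent.
    """
    best_clade = _clade_with(pairing.best_split, target)
    worst_clade = _clade_with(pairing.worst_split, target)
    out = {target}
    out |= best_clade.sibling_set(target)
    out |= worst_clade.sibling_set(target)
    return frozenset(out)


def _clade_with(split: tuple[Clade, Clade], target: str) -> Clade:
    for clade in split:
        if target in clade.leaves:
            return clade
    raise DataError(f"target {target!r} is not a leaf of the split")


@dataclass
class SelectionResult:
    """SM1/SM2 outputs with provenance, plus the chosen split per subset."""

    categories: dict[str, SM1CategoryResult]
    sm2_lists: dict[tuple[str, str], frozenset[str]]  # (category, target) -> set
    s_clade: frozenset[str]
    s_criterion: frozenset[str]
    r: frozenset[str]
    provenance: dict[str, set[str]]
    splits: dict[str, tuple[frozenset[str], frozenset[str]]]  # subset label -> leaf sets
    targets: tuple[str, ...] = ()
    models: dict[str, Phylogram] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "s_clade": sorted(self.s_clade),
            "s_criterion": sorted(self.s_criterion),
            "r": sorted(self.r),
            "targets": list(self.targets),
            "categories": {
                cat: {"s1": sorted(res.s1), "s2": sorted(res.s2),
                      "congruence": res.pairing.congruence,
                      "unpaired": sorted(res.unpaired)}
                for cat, res in self.categories.items()},
            "sm2": {f"{cat}:{target}": sorted(sel)
                    for (cat, target), sel in self.sm2_lists.items()},
            "provenance": {feat: sorted(tags)
                           for feat, tags in sorted(self.provenance.items())},
            "splits": {label: [sorted(c1), sorted(c2)]
                       for label, (c1, c2) in self.splits.items()},
        }
        return json.dumps(payload, indent=2)


def select_from_models(models: dict[str, Phylogram],
                       targets: Sequence[str] = ()) -> SelectionResult:
    """Run SM1 (and SM2 per target) on six already-built phylograms."""
    categories: dict[str, SM1CategoryResult] = {}
    sm2_lists: dict[tuple[str, str], frozenset[str]] = {}
    provenance: dict[str, set[str]] = {}
    splits: dict[str, tuple[frozenset[str], frozenset[str]]] = {}

    for cat in CATEGORIES:
        res = sm1(models[f"B{cat}"], models[f"W{cat}"], cat)
        categories[cat] = res
        bs, ws = res.pairing.best_split, res.pairing.worst_split
        splits[f"B{cat}"] = (bs[0].leaves, bs[1].leaves)
        splits[f"W{cat}"] = (ws[0].leaves, ws[1].leaves)
        for name, part in (("p1", res.s1), ("p2", res.s2)):
            for feat in part:
                provenance.setdefault(feat, set()).add(f"SM1:{cat}:{name}")
        for target in targets:
            sel = sm2(res.pairing, target)
            sm2_lists[(cat, target)] = sel
            for feat in sel:
                provenance.setdefault(feat, set()).add(f"SM2:{cat}:{target}")

    s_clade = frozenset().union(*(res.selected for res in categories.values()))
    s_criterion = (frozenset().union(*sm2_lists.values())
                   if sm2_lists else frozenset())
    return SelectionResult(categories=categories, sm2_lists=sm2_lists,
                           s_clade=s_clade, s_criterion=s_criterion,
                           r=s_clade | s_criterion, provenance=provenance,
                           splits=splits, targets=tuple(targets), models=models)


def select_features(table: FeatureTable, subsets: RankedSubsets,
                    targets: Sequence[str] = (), compressor: str = "zlib",
                    objects: Sequence[str] | None = None) -> SelectionResult:
    """Full sensitivity stage: build the six models, run SM1 and SM2, union.

    ``targets`` may be empty (SM1-only mode, s_criterion empty); typically it
    holds the criterion column, plus any further domain-suggested leaves.
    """
    if objects is None:
        objects = model_object_columns(table)
    for target in targets:
        if target not in objects:
            raise DataError(f"target {target!r} is not a model object column")
    models = {label: build_model(table, subsets[label], compressor, objects)
              for label in SUBSET_LABELS}
    return select_from_models(models, targets)
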