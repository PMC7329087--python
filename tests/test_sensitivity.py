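import numpy as np
import pytest

from fsopa.errors import DataError
from fsopa.sensitivity import (longest_path, pair_by_congruence, sm1, sm2,
                               split_middle, select_from_models)
from fsopa.synth import random_phylogram, toy_phylograms
from fsopa.tree import Phylogram

from _oracles import diameter_endpoints_bruteforce, sibling_sets_bruteforce


def caterpillar(names):
    """Caterpillar tree: leaves hang off a path of internal nodes."""
    n = len(names)
    edges = [(0, n, 1), (1, n, 1), (n - 1, 2 * n - 3, 1), (n - 2, 2 * n - 3, 1)]
    for i in range(2, n - 2):
        edges.append((i, n + i - 1, 1))
    for k in range(n, 2 * n - 3):
        edges.append((k, k + 1, 1))
    return Phylogram.from_edges(edges, dict(enumerate(names)))


class TestLongestPath:
    def test_two_leaf_tree(self):
        t = Phylogram.from_edges([(0, 1, 1.0)], {0: "a", 1: "b"})
        assert len(longest_path(t)) == 2

    def test_balanced_four_leaf_tie_break(self):
        t = Phylogram.from_edges(
            [(0, 4, 1), (1, 4, 1), (2, 5, 1), (3, 5, 1), (4, 5, 1)],
            {0: "a", 1: "b", 2: "c", 3: "d"})
        path = longest_path(t)
        assert len(path) == 4  # 3 edges
        # lexicographically smallest endpoint pair among the four candidates
        assert (t.node_name(path[0]), t.node_name(path[-1])) == ("a", "c")

    def test_caterpillar_matches_bruteforce_diameter(self, rng):
        t = caterpillar(list("abcdef"))
        leaves = {t.node_name(n): n for n in t.graph.nodes
                  if t.node_name(n) is not None}
        best, pairs = diameter_endpoints_bruteforce(t.graph, leaves)
        path = longest_path(t)
        assert len(path) - 1 == best
        assert (t.node_name(path[0]), t.node_name(path[-1])) == min(pairs)


class TestSplitMiddle:
    def test_odd_diameter_unique_middle(self):
        t = caterpillar(list("abcdef"))  # diameter 5 edges
        splits = split_middle(t)
        assert len(splits) == 1
        c1, c2 = splits[0]
        assert c1.leaves | c2.leaves == set("abcdef")
        assert not (c1.leaves & c2.leaves)

    def test_even_diameter_two_candidates(self):
        t = toy_phylograms("clade").worst  # diameter 6 edges
        assert len(split_middle(t)) == 2

    def test_two_leaf_base_case(self):
        t = Phylogram.from_edges([(0, 1, 1.0)], {0: "a", 1: "b"})
        (c1, c2), = split_middle(t)
        assert c1.leaves == {"a"} and c2.leaves == {"b"}


class TestCongruence:
    def test_identical_splits_pair_with_themselves(self):
        t = toy_phylograms("clade").best
        pairing = pair_by_congruence(split_middle(t), split_middle(t))
        assert pairing.congruence == len(pairing.p1[0].leaves)
        assert pairing.p1[0].leaves == pairing.p1[1].leaves

    def test_crossed_splits_resolved_by_tie_rule(self):
        def two_cherry_tree(pairs):
            (a, b), (c, d) = pairs
            return Phylogram.from_edges(
                [(0, 4, 1), (1, 4, 1), (2, 5, 1), (3, 5, 1), (4, 5, 1)],
                {0: a, 1: b, 2: c, 3: d})
        best = two_cherry_tree([("A", "B"), ("C", "D")])
        worst = two_cherry_tree([("A", "C"), ("B", "D")])
        pairing = pair_by_congruence(split_middle(best), split_middle(worst))
        assert pairing.congruence == 1

    def test_leaf_universe_mismatch_rejected(self):
        a = toy_phylograms("clade").best
        b = random_phylogram(8, np.random.default_rng(0))
        with pytest.raises(DataError):
            pair_by_congruence(split_middle(a), split_middle(b))


class TestSiblingSets:
    def test_cherry_and_nested_clade(self):
        fx = toy_phylograms("clade")
        (c1, c2), = split_middle(fx.best)
        clade = c1 if "A" in c1.leaves else c2
        assert clade.sibling_set("A") == {"B"}
        other = c2 if clade is c1 else c1
        assert other.sibling_set("E") == {"F"}

    def test_singleton_clade_empty_sibling_set(self):
        t = Phylogram.from_edges([(0, 1, 1.0)], {0: "a", 1: "b"})
        (c1, _), = split_middle(t)
        assert c1.sibling_set("a") == frozenset()

    def test_matches_bruteforce_on_random_clades(self, rng):
        for seed in range(10):
            t = random_phylogram(9, np.random.default_rng(seed))
            for clade in split_middle(t)[0]:
                names = {t.leaf_node(n): n for n in clade.leaves}
                oracle = sibling_sets_bruteforce(t.graph, set(clade.nodes),
                                                 clade.root, names)
                for leaf in clade.leaves:
                    assert clade.sibling_set(leaf) == oracle[leaf], leaf


class TestSM1:
    def test_identical_trees_select_nothing(self):
        for seed in range(25):
            t = random_phylogram(int(np.random.default_rng(seed).integers(4, 12)),
                                 np.random.default_rng(seed))
            res = sm1(t, t)
            assert res.selected == frozenset()

    def test_toy_clade_fixture(self):
        fx = toy_phylograms("clade")
        res = sm1(fx.best, fx.worst)
        assert res.selected == fx.expected == frozenset("AB")
        assert res.s2 == frozenset()

    def test_symmetric_under_best_worst_exchange(self):
        for seed in range(15):
            rng = np.random.default_rng(seed)
            a = random_phylogram(8, rng)
            b = random_phylogram(8, np.random.default_rng(seed + 1000))
            assert sm1(a, b).selected == sm1(b, a).selected

    def test_clades_partition_leaves(self):
        fx = toy_phylograms("clade")
        res = sm1(fx.best, fx.worst)
        for a, b in (res.pairing.best_split, res.pairing.worst_split):
            assert a.leaves | b.leaves == set("ABCDEFGH")
            assert not (a.leaves & b.leaves)

    def test_differing_leaf_sets_rejected(self):
        a = random_phylogram(6, np.random.default_rng(0))
        b = random_phylogram(7, np.random.default_rng(1))
        with pytest.raises(DataError):
            sm1(a, b)


class TestSM2:
    def test_toy_criterion_fixture(self):
        fx = toy_phylograms("criterion")
        res = sm1(fx.best, fx.worst)
        assert sm2(res.pairing, fx.target) == fx.expected == frozenset("ABC")

    def test_identical_trees_target_plus_sibling_subtree(self):
        fx = toy_phylograms("clade")
        res = sm1(fx.best, fx.best)
        assert sm2(res.pairing, "A") == {"A", "B"}
        assert sm2(res.pairing, "E") == {"E", "F"}

    def test_missing_target_rejected(self):
        fx = toy_phylograms("clade")
        res = sm1(fx.best, fx.worst)
        with pytest.raises(DataError):
            sm2(res.pairing, "Z")


class TestSelection:
    def _models(self, best, worst):
        return {f"{side}{cat}": tree
                for cat in ("2C", "4C", "8C")
                for side, tree in (("B", best), ("W", worst))}

    def test_identical_models_no_targets_empty_r(self):
        t = random_phylogram(8, np.random.default_rng(5))
        sel = select_from_models(self._models(t, t), targets=())
        assert sel.r == frozenset()

    def test_identical_models_with_target(self):
        fx = toy_phylograms("clade")
        sel = select_from_models(self._models(fx.best, fx.best), targets=["A"])
        assert sel.s_clade == frozenset()
        assert sel.r == sel.s_criterion == {"A", "B"}

    def test_union_and_provenance_cover_r(self):
        fx = toy_phylograms("criterion")
        sel = select_from_models(self._models(fx.best, fx.worst), targets=["A"])
        assert sel.r == sel.s_clade | sel.s_criterion
        assert set(sel.provenance) == set(sel.r)
        assert sel.r <= set("ABCDEFGH")

    def test_json_report_lists_all_sets(self):
        import json
        fx = toy_phylograms("criterion")
        sel = select_from_models(self._models(fx.best, fx.worst), targets=["A"])
        payload = json.loads(sel.to_json())
        assert payload["r"] == sorted(sel.r)
        assert set(payload["splits"]) == set(self._models(fx.best, fx.worst))
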