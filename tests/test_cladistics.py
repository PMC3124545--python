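import itertools

import numpy as np
import pytest

from wingshape import synthetic
from wingshape.cladistics import (apply_support, bootstrap_support,
                                  character_bounds, ci_ri, exhaustive_search,
                                  fitch_length, heuristic_search, map_changes,
                                  reroot_at_outgroup, strict_consensus)
from wingshape.formats import CharacterMatrix, read_newick
from wingshape.trees import robinson_foulds


def matrix_from_rows(rows: dict[str, str]) -> CharacterMatrix:
    taxa = list(rows)
    states = [[-1 if ch == "?" else int(ch) for ch in s]
              for s in rows.values()]
    return CharacterMatrix(taxa, np.array(states, dtype=np.int8))


def brute_force_length(tree, matrix):
    """Oracle: minimize changes over every assignment of states to the
    internal nodes (enumeration; exponential, tiny trees only)."""
    observed = [sorted({v for v in matrix.states[:, c] if v >= 0})
                for c in range(matrix.n_characters)]
    internal = [n for n in tree.postorder() if not n.is_leaf]
    tip_row = {t: i for i, t in enumerate(matrix.taxa)}
    total = 0
    for c in range(matrix.n_characters):
        states = observed[c]
        best = np.inf
        for assign in itertools.product(states, repeat=len(internal)):
            lookup = {id(n): s for n, s in zip(internal, assign)}
            cost = 0
            for node in tree.postorder():
                if node.parent is None:
                    continue
                ps = lookup[id(node.parent)]
                if node.is_leaf:
                    v = matrix.states[tip_row[node.name], c]
                    if v >= 0 and v != ps:
                        cost += 1
                elif lookup[id(node)] != ps:
                    cost += 1
            best = min(best, cost)
        total += best
    return total


class TestFitchLength:
    def test_four_taxon_hand_examples(self):
        tree = read_newick("((A,B),(C,D));")
        m1 = matrix_from_rows({"A": "0", "B": "0", "C": "1", "D": "1"})
        assert fitch_length(tree, m1) == 1
        m2 = matrix_from_rows({"A": "0", "B": "1", "C": "0", "D": "1"})
        assert fitch_length(tree, m2) == 2

    def test_constant_character_zero(self):
        tree = read_newick("((A,B),(C,D));")
        m = matrix_from_rows({"A": "7", "B": "7", "C": "7", "D": "7"})
        assert fitch_length(tree, m) == 0

    def test_missing_data_never_forces_changes(self):
        tree = read_newick("((A,B),(C,D));")
        m = matrix_from_rows({"A": "0", "B": "?", "C": "1", "D": "?"})
        assert fitch_length(tree, m) == 1

    def test_matches_enumeration_oracle_random(self):
        rng = np.random.default_rng(2)
        tree = read_newick("(((A,B),C),(D,E));")
        for _ in range(5):
            states = rng.integers(0, 3, size=(5, 4))
            m = CharacterMatrix(list("ABCDE"), states.astype(np.int8))
            assert fitch_length(tree, m) == brute_force_length(tree, m)

    def test_root_independence(self, small_bundle):
        m = small_bundle.matrix
        res = exhaustive_search(m) if m.n_taxa <= 8 else None
        tree = res.best_trees[0]
        rerooted = reroot_at_outgroup(tree, m.taxa[3])
        assert fitch_length(rerooted, m) == fitch_length(tree, m)

    def test_taxon_mismatch_reported(self):
        tree = read_newick("((A,B),(C,X));")
        m = matrix_from_rows({"A": "0", "B": "0", "C": "1", "D": "1"})
        with pytest.raises(ValueError, match="X"):
            fitch_length(tree, m)


class TestCharacterBounds:
    def test_direct_formulas(self):
        m = matrix_from_rows({"A": "00", "B": "00", "C": "10", "D": "10"})
        mins, maxs = character_bounds(m)
        assert mins.tolist() == [1, 0]
        assert maxs.tolist() == [2, 0]

    def test_with_missing_and_multistate(self):
        # states {0,1,2,2,?}: min = 2, max = 4 - 2 = 2
        m = matrix_from_rows({"A": "0", "B": "1", "C": "2", "D": "2", "E": "?"})
        mins, maxs = character_bounds(m)
        assert mins[0] == 2 and maxs[0] == 2
        # max over all trees by enumeration on the 4 scored taxa
        worst = 0
        sub = matrix_from_rows({"A": "0", "B": "1", "C": "2", "D": "2"})
        for nwk in ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]:
            worst = max(worst, fitch_length(read_newick(nwk), sub))
        assert worst == maxs[0]


class TestCiRi:
    def test_perfect_phylogeny(self):
        m = matrix_from_rows({"A": "00", "B": "01", "C": "11", "D": "11"})
        res = exhaustive_search(m)
        mins, _ = character_bounds(m)
        assert res.best_length == mins.sum()
        stats = ci_ri(res.best_length, m)
        assert stats.ci == pytest.approx(1.0)
        assert stats.ri == pytest.approx(1.0)

    def test_worst_tree_gives_ri_zero(self):
        m = matrix_from_rows({"A": "0", "B": "0", "C": "1", "D": "1"})
        _, maxs = character_bounds(m)
        stats = ci_ri(int(maxs.sum()), m)
        assert stats.ri == pytest.approx(0.0)

    def test_bounds_invariants(self, small_bundle):
        m = small_bundle.matrix
        res = exhaustive_search(m)
        mins, maxs = character_bounds(m)
        assert mins.sum() <= res.best_length <= maxs.sum()
        stats = ci_ri(res.best_length, m)
        assert 0 < stats.ci <= 1
        assert 0 <= stats.ri <= 1


class TestHeuristicSearch:
    @pytest.mark.parametrize("swapper", ["spr", "tbr"])
    def test_equals_exhaustive_on_six_taxa(self, swapper):
        rng = np.random.default_rng(17)
        for trial in range(3):
            states = rng.integers(0, 2, size=(6, 12)).astype(np.int8)
            m = CharacterMatrix([f"t{i}" for i in range(6)], states)
            exact = exhaustive_search(m)
            heur = heuristic_search(m, n_addition_replicates=5,
                                    swapper=swapper, seed=trial)
            assert heur.best_length == exact.best_length
            heur_keys = {frozenset(t.bipartitions()) for t in heur.best_trees}
            exact_keys = {frozenset(t.bipartitions()) for t in exact.best_trees}
            assert heur_keys == exact_keys

    def test_perfect_phylogeny_ci_one(self):
        m = matrix_from_rows({"A": "000", "B": "100", "C": "110", "D": "111",
                              "E": "111"})
        res = heuristic_search(m, n_addition_replicates=3, seed=0)
        mins, _ = character_bounds(m)
        assert res.best_length == mins.sum()
        assert res.stats.ci == pytest.approx(1.0)

    def test_deterministic_under_seed(self, small_bundle):
        r1 = heuristic_search(small_bundle.matrix, n_addition_replicates=3,
                              seed=5, swapper="spr")
        r2 = heuristic_search(small_bundle.matrix, n_addition_replicates=3,
                              seed=5, swapper="spr")
        assert r1.best_length == r2.best_length
        assert [t.to_newick() for t in r1.best_trees] == \
            [t.to_newick() for t in r2.best_trees]

    def test_outgroup_rooting(self, small_bundle):
        og = small_bundle.matrix.taxa[0]
        res = heuristic_search(small_bundle.matrix, n_addition_replicates=2,
                               seed=1, swapper="spr", outgroup=og)
        for tree in res.best_trees:
            names = [c.name for c in tree.root.children]
            assert og in names

    def test_more_effort_never_worse(self, small_bundle):
        lens = []
        for reps in (1, 4):
            res = heuristic_search(small_bundle.matrix, swapper="spr",
                                   n_addition_replicates=reps, seed=9)
            lens.append(res.best_length)
        assert lens[1] <= lens[0]


class TestBootstrap:
    def test_unanimous_characters_full_support(self):
        rows = {"A": "0" * 20, "B": "0" * 20, "C": "1" * 20, "D": "1" * 20,
                "E": "1" * 20}
        m = matrix_from_rows(rows)
        freqs = bootstrap_support(m, n_reps=30, seed=4, addition_replicates=2)
        clade = frozenset({"C", "D", "E"})
        assert freqs.get(clade, 0) == pytest.approx(1.0)

    def test_deterministic_under_seed(self, small_bundle):
        f1 = bootstrap_support(small_bundle.matrix, n_reps=10, seed=8,
                               addition_replicates=1)
        f2 = bootstrap_support(small_bundle.matrix, n_reps=10, seed=8,
                               addition_replicates=1)
        assert f1 == f2

    def test_noise_matrix_no_strong_support(self):
        rng = np.random.default_rng(123)
        states = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        m = CharacterMatrix([f"t{i}" for i in range(8)], states)
        freqs = bootstrap_support(m, n_reps=50, seed=6, addition_replicates=1)
        assert all(f <= 0.95 for f in freqs.values())

    def test_apply_support_annotates(self, small_bundle):
        res = heuristic_search(small_bundle.matrix, n_addition_replicates=2,
                               seed=1, swapper="spr")
        freqs = bootstrap_support(small_bundle.matrix, n_reps=20, seed=2,
                                  addition_replicates=1)
        tree = apply_support(res.best_trees[0].copy(), freqs)
        supports = [n.support for n in tree.postorder()
                    if not n.is_leaf and n.support is not None]
        assert supports and all(0 <= s <= 100 for s in supports)


class TestStrictConsensus:
    def test_identical_trees_unchanged(self):
        t = read_newick("((A,B),((C,D),E));")
        cons, n_collapsed = strict_consensus([t, t.copy()])
        assert n_collapsed == 0
        assert cons.bipartitions() == t.bipartitions()

    def test_one_conflicting_edge_collapsed(self):
        t1 = read_newick("(((A,B),C),(D,E));")
        t2 = read_newick("(((A,C),B),(D,E));")
        cons, n_collapsed = strict_consensus([t1, t2])
        assert n_collapsed == 1
        assert cons.bipartitions() == {frozenset({"D", "E"})}

    def test_star_absorbs_everything(self):
        star = read_newick("(A,B,C,D,E);")
        t = read_newick("(((A,B),C),(D,E));")
        cons, _ = strict_consensus([star, t])
        assert cons.bipartitions() == set()

    def test_tip_mismatch_error(self):
        with pytest.raises(ValueError, match="tip sets"):
            strict_consensus([read_newick("((A,B),C);"),
                              read_newick("((A,B),D);")])


class TestMapChanges:
    def test_perfect_character_single_change(self):
        tree = read_newick("((A,B),(C,D));")
        m = matrix_from_rows({"A": "0", "B": "0", "C": "1", "D": "1"})
        changes = map_changes(tree, m)
        assert len(changes) == 1
        assert not changes[0].homoplasious
        assert {changes[0].from_state, changes[0].to_state} == {0, 1}

    def test_homoplasious_character_flagged(self):
        tree = read_newick("((A,B),(C,D));")
        m = matrix_from_rows({"A": "0", "B": "1", "C": "0", "D": "1"})
        changes = map_changes(tree, m)
        assert len(changes) == 2
        assert all(c.homoplasious for c in changes)

    def test_constant_character_no_changes(self):
        tree = read_newick("((A,B),(C,D));")
        m = matrix_from_rows({"A": "3", "B": "3", "C": "3", "D": "3"})
        assert map_changes(tree, m) == []

    def test_change_count_equals_fitch_length(self, small_bundle):
        res = exhaustive_search(small_bundle.matrix)
        tree = res.best_trees[0]
        changes = map_changes(tree, small_bundle.matrix)
        assert len(changes) == res.best_length

    def test_polytomy_rejected(self):
        tree = read_newick("(A,B,C,D);")
        m = matrix_from_rows({"A": "0", "B": "0", "C": "1", "D": "1"})
        with pytest.raises(ValueError, match="binary"):
            map_changes(tree, m)
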