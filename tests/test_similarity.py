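"""MP3 score computation: examples, invariants, and oracle agreement."""

import itertools
import math

import numpy as np
import pytest

from conftest import chain_tree, random_labeled_tree
from mp3sim.similarity import (
    InsufficientSharedLabelsError,
    SigmoidParams,
    mp3_score,
    shared_node_pairs,
    sigmoid,
    similarity_matrix,
    triple_scores,
)
from mp3sim.treeio import LabeledTree, parse_dot
from oracle import brute_force_mp3


class TestTripleScores:
    @pytest.mark.parametrize(
        "m1, m2, expected",
        [
            ({"s1": 3, "s2": 2}, {"s1": 3, "s2": 2}, (5, 5)),   # identical
            ({"s1": 2}, {"s2": 3}, (0, 3)),                      # disjoint
            ({"s1": 2, "s2": 1}, {"s1": 1, "s3": 4}, (1, 5)),    # mixed
            ({}, {"s1": 2}, (0, 2)),                             # one empty
        ],
    )
    def test_multiset_arithmetic(self, m1, m2, expected):
        assert triple_scores(m1, m2) == expected


class TestSigmoid:
    def test_centered_at_half(self):
        assert sigmoid(0.5) == pytest.approx(0.5)

    def test_closed_form_at_one(self):
        assert sigmoid(1.0) == pytest.approx(1 / (1 + math.exp(-5)), rel=1e-12)
        assert sigmoid(1.0) == pytest.approx(0.993307, abs=5e-7)

    def test_symmetry(self):
        assert sigmoid(0.0) == pytest.approx(1 - sigmoid(1.0), rel=1e-12)

    def test_mu_validated(self):
        with pytest.raises(ValueError):
            SigmoidParams(mu=0)


class TestMP3Score:
    def test_identical_trees_score_one(self):
        rng = np.random.default_rng(11)
        t = random_labeled_tree(rng, 12, label_pool=[f"m{i}" for i in range(9)])
        r = mp3_score(t, t)
        assert r.mp3_intersection == 1.0
        assert r.mp3_union == 1.0
        assert r.mp3_geometric == 1.0
        assert r.mp3_sigmoid == 1.0
        assert r.numerator_sum == r.denominator_sum == r.union_denominator_sum

    def test_chain_vs_star_scores_zero(self, chain3, star3):
        """The single shared triple induces a chain in one tree and a star
        in the other: disjoint configurations, every score 0."""
        r = mp3_score(chain3, star3)
        assert (r.mp3_intersection, r.mp3_union, r.mp3_geometric,
                r.mp3_sigmoid) == (0.0, 0.0, 0.0, 0.0)
        assert r.numerator_sum == 0 and r.denominator_sum == 1

    def test_sigmoid_blend_formula_at_half_union(self):
        """MP3∩ = 1, MP3∪ = 1/2 gives MP3σ = 1/2 + σ(1)·min{1/2, 1/2}.

        Realized exactly: a 5-label chain against the same chain extended by
        one private-label leaf — shared triples agree perfectly (ΣN = ΣD_I =
        C(5,3) = 10) and the private label adds C(6,3) − C(5,3) = 10 union-only
        triples of unit denominator, halving the union ratio.
        """
        t1 = chain_tree(5)
        parent = dict(t1.parent)
        labels = dict(t1.labels_of)
        parent["x"] = "c4"
        labels["x"] = frozenset(["private"])
        t2 = LabeledTree(parent=parent, root="c0", labels_of=labels)
        r = mp3_score(t1, t2)
        assert r.mp3_intersection == 1.0
        assert r.mp3_union == 0.5
        assert r.mp3_sigmoid == pytest.approx(0.5 + sigmoid(1.0) * 0.5, rel=1e-12)
        assert r.mp3_sigmoid == pytest.approx(0.9967, abs=5e-5)

    def test_insufficient_shared_labels(self):
        t1 = parse_dot('digraph { 1 [label="a"]; 2 [label="b"]; 1 -> 2; }')
        t2 = parse_dot('digraph { 1 [label="a"]; 2 [label="x"]; 1 -> 2; }')
        with pytest.raises(InsufficientSharedLabelsError, match="share only 1"):
            mp3_score(t1, t2)

    def test_agrees_with_brute_force_on_poly_multilabeled_pairs(self):
        """Vectorized implementation vs independent subtree-materializing
        oracle on random multilabeled trees with poly-occurring labels."""
        rng = np.random.default_rng(5)
        pool = [f"m{i}" for i in range(7)]
        trees = [
            random_labeled_tree(rng, int(rng.integers(3, 9)), label_pool=pool)
            for _ in range(8)
        ]
        checked = 0
        for t1, t2 in itertools.combinations(trees, 2):
            try:
                expected = brute_force_mp3(t1, t2)
            except ValueError:
                with pytest.raises(InsufficientSharedLabelsError):
                    mp3_score(t1, t2)
                continue
            r = mp3_score(t1, t2)
            got = (r.mp3_intersection, r.mp3_union, r.mp3_geometric, r.mp3_sigmoid)
            assert got == pytest.approx(expected, rel=1e-12)
            checked += 1
        assert checked >= 10

    def test_bounds_ordering_and_symmetry(self):
        rng = np.random.default_rng(17)
        pool = [f"m{i}" for i in range(15)]
        for _ in range(30):
            t1 = random_labeled_tree(rng, int(rng.integers(4, 15)), label_pool=pool)
            t2 = random_labeled_tree(rng, int(rng.integers(4, 15)), label_pool=pool)
            try:
                r = mp3_score(t1, t2)
            except InsufficientSharedLabelsError:
                continue
            assert 0 <= r.mp3_union <= r.mp3_sigmoid <= r.mp3_intersection <= 1
            assert r.mp3_union <= r.mp3_geometric <= r.mp3_intersection
            assert r.mp3_geometric == pytest.approx(
                math.sqrt(r.mp3_intersection * r.mp3_union), rel=1e-12)
            rr = mp3_score(t2, t1)
            assert rr == r

    def test_chain_raising_monotone_decrease(self):
        """Raising the deepest label of a 6-node chain toward the root
        produces strictly decreasing similarity to the base chain."""
        base = chain_tree(6)
        scores = []
        for new_parent in ("c3", "c2", "c1", "c0"):
            parent = dict(base.parent)
            parent["c5"] = new_parent
            variant = LabeledTree(parent=parent, root="c0",
                                  labels_of=base.labels_of)
            scores.append(mp3_score(base, variant).mp3_sigmoid)
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert scores[0] < 1.0

    def test_label_duplication_strictly_changes_score(self):
        """Duplicating labels of one tree never leaves the score fixed at 1."""
        rng = np.random.default_rng(23)
        base = random_labeled_tree(rng, 10)
        labels = {n: set(s) for n, s in base.labels_of.items()}
        # duplicate two labels onto other nodes
        labels["n005"].add("L1")
        labels["n009"].add("L2")
        dup = LabeledTree(parent=base.parent, root=base.root,
                          labels_of={n: frozenset(s) for n, s in labels.items()})
        r = mp3_score(base, dup)
        assert r.mp3_sigmoid < 1.0


class TestSharedNodePairs:
    def test_identical_one_node_trees(self):
        t = parse_dot('digraph { 1 [label="a,b,c"]; }')
        assert shared_node_pairs(t, t) == (3, 3)

    def test_pair_split_across_nodes(self):
        t1 = parse_dot('digraph { 1 [label="a,b"]; }')
        t2 = parse_dot('digraph { 1 [label="a"]; 2 [label="b"]; 1 -> 2; }')
        assert shared_node_pairs(t1, t2) == (0, 1)

    def test_disjoint_labels(self, chain3):
        t2 = parse_dot('digraph { 1 [label="x,y"]; }')
        assert shared_node_pairs(chain3, t2) == (0, 1)


class TestSimilarityMatrix:
    def test_three_copies_all_ones(self, chain3):
        df = similarity_matrix([chain3, chain3, chain3])
        assert df.shape == (3, 3)
        assert np.allclose(df.to_numpy(), 1.0)

    def test_chain_star_off_diagonal_zero(self, chain3, star3):
        df = similarity_matrix([chain3, star3])
        assert df.iloc[0, 1] == 0.0
        assert df.iloc[0, 0] == df.iloc[1, 1] == 1.0

    def test_symmetric_with_nan_for_undefined_pairs(self, chain3):
        other = parse_dot('digraph { 1 [label="p"]; 2 [label="q"]; 3 [label="r"];'
                          " 1 -> 2; 2 -> 3; }")
        with pytest.warns(UserWarning, match="skipped"):
            df = similarity_matrix([chain3, other, chain3])
        m = df.to_numpy()
        assert np.isnan(m[0, 1]) and np.isnan(m[1, 0])
        assert m[0, 2] == 1.0

    def test_mode_selection(self, chain3, star3):
        for mode in ("sigmoid", "intersection", "union", "geometric"):
            df = similarity_matrix([chain3, star3], mode=mode)
            assert df.iloc[0, 1] == 0.0
        with pytest.raises(ValueError):
            similarity_matrix([chain3, star3], mode="nope")
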