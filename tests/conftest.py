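"""Shared fixtures: small reference trees and random-tree generation."""

from __future__ import annotations

import numpy as np
import pytest

from mp3sim.treeio import LabeledTree, parse_dot

CHAIN_DOT = """
digraph chain {
    1 [label="a"]; 2 [label="b"]; 3 [label="c"];
    1 -> 2; 2 -> 3;
}
"""

STAR_DOT = """
digraph star {
    1 [label="a"]; 2 [label="b"]; 3 [label="c"];
    1 -> 2; 1 -> 3;
}
"""


@pytest.fixture
def chain3() -> LabeledTree:
    """Chain {a} -> {b} -> {c}."""
    return parse_dot(CHAIN_DOT, "chain")


@pytest.fixture
def star3() -> LabeledTree:
    """Root {a} with children {b}, {c}."""
    return parse_dot(STAR_DOT, "star")


def random_labeled_tree(
    rng: np.random.Generator,
    n_nodes: int,
    label_pool: list[str] | None = None,
    max_labels_per_node: int = 2,
) -> LabeledTree:
    """Random rooted tree, optionally multilabeled/poly-occurring.

    With a ``label_pool``, node label sets are sampled from the pool with
    replacement across nodes (so poly-occurrences arise naturally); without
    one, every node gets a unique single label.
    """
    parent: dict[str, str] = {}
    labels: dict[str, frozenset[str]] = {}
    for i in range(n_nodes):
        nid = f"n{i:03d}"
        if i > 0:
            parent[nid] = f"n{int(rng.integers(i)):03d}"
        if label_pool is None:
            labels[nid] = frozenset([f"L{i}"])
        else:
            k = int(rng.integers(1, max_labels_per_node + 1))
            k = min(k, len(label_pool))
            picked = rng.choice(len(label_pool), size=k, replace=False)
            labels[nid] = frozenset(label_pool[int(j)] for j in picked)
    return LabeledTree(parent=parent, root="n000", labels_of=labels)


def chain_tree(k: int, prefix: str = "a") -> LabeledTree:
    """Linear chain of k single-label nodes: {a0} -> {a1} -> ... -> {a(k-1)}."""
    parent = {f"c{i}": f"c{i-1}" for i in range(1, k)}
    labels = {f"c{i}": frozenset([f"{prefix}{i}"]) for i in range(k)}
    return LabeledTree(parent=parent, root="c0", labels_of=labels, name=f"chain{k}")
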