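"""Independent brute-force oracle for triple-topology classification.

Classifies the minimal topology of a node triple by explicitly materializing
the spanning subtree: take the three nodes and their three pairwise LCAs
(LCAs found by naive ancestor-walks, no index structure), connect each kept
node to its nearest kept proper ancestor, and canonically encode the result
as a slot-annotated rooted unordered tree.  Degree-2 contraction is implicit:
only the six (or fewer, under coincidence) relevant nodes are kept.

Also provides a naive per-pair MP3 computation built on this classification,
used to cross-check the vectorized implementation.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

from mp3sim.treeio import LabeledTree


def ancestors(tree: LabeledTree, node: str) -> list[str]:
    """node itself plus every ancestor, deepest first."""
    out = [node]
    while node in tree.parent:
        node = tree.parent[node]
        out.append(node)
    return out


def naive_lca(tree: LabeledTree, u: str, v: str) -> str:
    au = ancestors(tree, u)
    av = set(ancestors(tree, v))
    for x in au:
        if x in av:
            return x
    raise AssertionError("disconnected tree")


def minimal_topology(tree: LabeledTree, u: str, v: str, z: str):
    """Canonical slot-annotated minimal subtree of (u, v, z).

    Returns a hashable nested structure: each node encoded as
    (sorted slot marks, sorted child encodings); slot marks are 'a'/'b'/'c'
    for the first/second/third slot.  Two triples get equal encodings iff
    their contracted minimal subtrees, with slots marked, are isomorphic.
    """
    slots = {}
    for mark, node in zip("abc", (u, v, z)):
        slots.setdefault(node, []).append(mark)
    keep = {u, v, z}
    for x, y in itertools.combinations_with_replacement((u, v, z), 2):
        keep.add(naive_lca(tree, x, y))
    parent_in_keep = {}
    for n in keep:
        anc = [a for a in ancestors(tree, n)[1:] if a in keep]
        if anc:
            parent_in_keep[n] = anc[0]  # nearest kept proper ancestor
    # An unmarked LCA that is its parent's only kept child is contracted into
    # the parent (the configuration catalog does not distinguish whether the
    # lower pair's LCA coincides with the dominating node or sits strictly
    # below it).
    changed = True
    while changed:
        changed = False
        for n in sorted(keep):
            if n in slots or n not in parent_in_keep:
                continue
            par = parent_in_keep[n]
            siblings = [c for c, p in parent_in_keep.items() if p == par]
            if siblings == [n]:
                for c, p in list(parent_in_keep.items()):
                    if p == n:
                        parent_in_keep[c] = par
                keep.discard(n)
                del parent_in_keep[n]
                changed = True
                break
    roots = [n for n in keep if n not in parent_in_keep]
    assert len(roots) == 1

    def encode(n: str):
        children = sorted(
            encode(c) for c, p in parent_in_keep.items() if p == n
        )
        return (tuple(sorted(slots.get(n, []))), tuple(children))

    return encode(roots[0])


def shape_of(tree: LabeledTree, u: str, v: str, z: str):
    """Slot-permutation-quotiented (unordered-triple) configuration: replace
    slot marks by their count and take the canonical encoding."""

    def strip(enc):
        marks, children = enc
        return (len(marks), tuple(sorted(strip(c) for c in children)))

    return strip(minimal_topology(tree, u, v, z))


def label_multiset(tree: LabeledTree, a: str, b: str, c: str) -> Counter:
    """M_T(a, b, c) by explicit enumeration of occurrence combinations."""
    out: Counter = Counter()
    for u in tree.occurrences.get(a, ()):
        for v in tree.occurrences.get(b, ()):
            for z in tree.occurrences.get(c, ()):
                out[minimal_topology(tree, u, v, z)] += 1
    return out


def brute_force_mp3(tree1: LabeledTree, tree2: LabeledTree, mu: float = 10.0):
    """All four scores by direct per-triple multiset construction.

    Returns (intersection, union, geometric, sigmoid) or raises ValueError
    when fewer than three labels are shared.
    """
    shared = sorted(tree1.label_set & tree2.label_set)
    union = sorted(tree1.label_set | tree2.label_set)
    if len(shared) < 3:
        raise ValueError("insufficient shared labels")
    sum_n = sum_d_i = sum_d_j = 0
    for a, b, c in itertools.combinations(union, 3):
        m1 = label_multiset(tree1, a, b, c)
        m2 = label_multiset(tree2, a, b, c)
        d = max(sum(m1.values()), sum(m2.values()))
        n = sum(min(cnt, m2.get(sig, 0)) for sig, cnt in m1.items())
        in_both = all(lab in tree1.label_set and lab in tree2.label_set
                      for lab in (a, b, c))
        if in_both:
            sum_n += n
            sum_d_i += d
        sum_d_j += d
    inter = sum_n / sum_d_i
    uni = sum_n / sum_d_j
    geom = math.sqrt(inter * uni)
    sig = 1.0 / (1.0 + math.exp(-mu * (inter - 0.5)))
    return inter, uni, geom, uni + sig * min(inter - uni, uni)
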