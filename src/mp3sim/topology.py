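"""LCA queries and canonical classification of triple-induced topologies.

Given three label occurrences ``u, v, z`` in a rooted tree, the *minimal tree
topology* they induce is the smallest subtree spanning ``{u, v, z}`` and their
three pairwise lowest common ancestors, with unmarked degree-2 nodes
contracted.  For triples of distinct nodes this minimal topology falls into
exactly five shapes; allowing two or three of the occurrences to coincide on
one node (multilabeled trees) adds four more, for nine in total.

Rather than materializing the contracted subtree, a triple is classified in
O(1) from three LCA queries into a :class:`TripleSignature`: the ordered
pairwise ancestry relations plus the coincidence partition of the three
pairwise LCAs.  These two components determine the slot-annotated minimal
topology (the test suite verifies this against an independent subtree-building
oracle on all small trees).

Signatures are *slot-ordered*: the signature of ``(u, v, z)`` records which
slot sits where, because comparing two trees intersects the configuration
multisets of the *same* ordered label triple.  Quotienting by slot permutation
happens only in :func:`enumerate_shapes`.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .treeio import LabeledTree

__all__ = [
    "LCAIndex",
    "TripleSignature",
    "ConfigMultiset",
    "build_lca_index",
    "node_triple_signature",
    "label_triple_multiset",
    "enumerate_shapes",
]

# pairwise relation codes
SAME = 0          # the two slots occupy one node
FIRST_ANC = 1     # first node is a strict ancestor of the second
SECOND_ANC = 2    # second node is a strict ancestor of the first
INCOMPARABLE = 3  # neither is an ancestor of the other

_REL_NAMES = ("same-node", "first-is-strict-ancestor",
              "second-is-strict-ancestor", "incomparable")


class TripleSignature(NamedTuple):
    """Canonical encoding of the minimal topology of an ordered node triple.

    ``pair_relations`` holds the relation codes for the slot pairs
    (a,b), (a,c), (b,c); ``lca_partition`` assigns each of the pairwise LCAs
    LCA(a,b), LCA(a,c), LCA(b,c) a block index (first-occurrence order), so
    e.g. ``(0, 0, 1)`` means LCA(a,b) = LCA(a,c) != LCA(b,c).
    """

    pair_relations: tuple[int, int, int]
    lca_partition: tuple[int, int, int]

    def describe(self) -> str:
        rels = ", ".join(_REL_NAMES[r] for r in self.pair_relations)
        return f"relations=({rels}) lca_blocks={self.lca_partition}"

    @classmethod
    def from_code(cls, code: int) -> "TripleSignature":
        part = _PART_DECODE[code & 7]
        rels = code >> 3
        return cls(((rels >> 4) & 3, (rels >> 2) & 3, rels & 3), part)

    def to_code(self) -> int:
        r1, r2, r3 = self.pair_relations
        return ((r1 << 4) | (r2 << 2) | r3) << 3 | _PART_ENCODE[self.lca_partition]


# partition of the three LCAs by node identity, packed in 3 bits:
# bit0 = (l_ab == l_ac), bit1 = (l_ab == l_bc), bit2 = (l_ac == l_bc)
_PART_DECODE = {
    0: (0, 1, 2),
    1: (0, 0, 1),
    2: (0, 1, 0),
    4: (0, 1, 1),
    7: (0, 0, 0),
}
_PART_ENCODE = {v: k for k, v in _PART_DECODE.items()}


@dataclass
class LCAIndex:
    """Constant-time lowest-common-ancestor queries via Euler tour + sparse table.

    Preprocessing is O(n log n) in the node count; queries are O(1) and
    vectorized over numpy arrays of node indices.  Node ids are mapped to
    dense integer indices in sorted-id order (``node_index`` / ``index_node``).
    """

    tree: LabeledTree
    node_index: dict[str, int] = field(init=False)
    index_node: list[str] = field(init=False)
    depth: np.ndarray = field(init=False)
    _first: np.ndarray = field(init=False)
    _euler: np.ndarray = field(init=False)
    _sparse: np.ndarray = field(init=False)
    _log2: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        tree = self.tree
        nodes = sorted(tree.labels_of)
        self.index_node = nodes
        self.node_index = {nid: i for i, nid in enumerate(nodes)}
        n = len(nodes)
        children: list[list[int]] = [[] for _ in range(n)]
        for child, par in tree.parent.items():
            children[self.node_index[par]].append(self.node_index[child])
        for ch in children:
            ch.sort()
        depth = np.zeros(n, dtype=np.int64)
        euler: list[int] = []
        first = np.full(n, -1, dtype=np.int64)
        # iterative Euler tour (node pushed again after each child subtree)
        root = self.node_index[tree.root]
        stack: list[tuple[int, int]] = [(root, 0)]
        while stack:
            node, child_i = stack.pop()
            if child_i == 0:
                first[node] = len(euler)
            euler.append(node)
            if child_i < len(children[node]):
                stack.append((node, child_i + 1))
                c = children[node][child_i]
                depth[c] = depth[node] + 1
                stack.append((c, 0))
        self.depth = depth
        self._euler = np.asarray(euler, dtype=np.int64)
        self._first = first
        m = len(euler)
        edepth = depth[self._euler]
        self._edepth = edepth
        levels = max(1, m.bit_length())
        sparse = np.empty((levels, m), dtype=np.int64)
        sparse[0] = np.arange(m)
        for k in range(1, levels):
            half = 1 << (k - 1)
            span = m - (1 << k) + 1
            if span <= 0:
                sparse[k] = sparse[k - 1]
                continue
            left = sparse[k - 1, :span]
            right = sparse[k - 1, half:half + span]
            pick = edepth[left] <= edepth[right]
            sparse[k, :span] = np.where(pick, left, right)
            sparse[k, span:] = sparse[k - 1, span:]
        self._sparse = sparse
        log2 = np.zeros(m + 1, dtype=np.int64)
        for i in range(2, m + 1):
            log2[i] = log2[i >> 1] + 1
        self._log2 = log2

    # -- queries ---------------------------------------------------------------

    def lca_idx(self, u, v) -> np.ndarray:
        """Vectorized LCA on dense node indices."""
        u = np.asarray(u, dtype=np.int64)
        v = np.asarray(v, dtype=np.int64)
        l = self._first[u]
        r = self._first[v]
        lo = np.minimum(l, r)
        hi = np.maximum(l, r)
        k = self._log2[hi - lo + 1]
        edepth = self._edepth
        a = self._sparse[k, lo]
        b = self._sparse[k, hi - (1 << k) + 1]
        pos = np.where(edepth[a] <= edepth[b], a, b)
        return self._euler[pos]

    def lca(self, u: str, v: str) -> str:
        """LCA of two nodes by id."""
        try:
            ui = self.node_index[u]
            vi = self.node_index[v]
        except KeyError as exc:
            raise KeyError(f"node {exc.args[0]!r} not in tree") from None
        return self.index_node[int(self.lca_idx(ui, vi))]

    def signature_codes(self, u, v, z) -> np.ndarray:
        """Vectorized packed signature codes for ordered index triples.

        The code packs the three pairwise relation codes (2 bits each) and the
        LCA coincidence bits (3 bits); :meth:`TripleSignature.from_code`
        unpacks it.  Equal codes correspond exactly to equal signatures.
        """
        u = np.asarray(u, dtype=np.int64)
        v = np.asarray(v, dtype=np.int64)
        z = np.asarray(z, dtype=np.int64)
        l_ab = self.lca_idx(u, v)
        l_ac = self.lca_idx(u, z)
        l_bc = self.lca_idx(v, z)
        rel_ab = self._rel(u, v, l_ab)
        rel_ac = self._rel(u, z, l_ac)
        rel_bc = self._rel(v, z, l_bc)
        part = (
            (l_ab == l_ac).astype(np.int64)
            | ((l_ab == l_bc).astype(np.int64) << 1)
            | ((l_ac == l_bc).astype(np.int64) << 2)
        )
        # One slot strictly dominating the other two mutually-incomparable
        # slots: the lower pair's LCA is absorbed into the dominating node
        # (the five/nine-configuration catalog does not distinguish whether
        # that LCA coincides with it or lies strictly below), so the
        # partition is normalized to all-coincident.
        dom = (
            ((rel_ab == FIRST_ANC) & (rel_ac == FIRST_ANC) & (rel_bc == INCOMPARABLE))
            | ((rel_ab == SECOND_ANC) & (rel_bc == FIRST_ANC) & (rel_ac == INCOMPARABLE))
            | ((rel_ac == SECOND_ANC) & (rel_bc == SECOND_ANC) & (rel_ab == INCOMPARABLE))
        )
        part[dom] = 7
        return (((rel_ab << 4) | (rel_ac << 2) | rel_bc) << 3) | part

    @staticmethod
    def _rel(x, y, lca) -> np.ndarray:
        same = x == y
        x_anc = (lca == x) & ~same
        y_anc = (lca == y) & ~same
        rel = np.full(np.shape(x), INCOMPARABLE, dtype=np.int64)
        rel[y_anc] = SECOND_ANC
        rel[x_anc] = FIRST_ANC
        rel[same] = SAME
        return rel


def build_lca_index(tree: LabeledTree) -> LCAIndex:
    """Preprocess a tree for constant-time LCA and signature queries."""
    return LCAIndex(tree)


def node_triple_signature(index: LCAIndex, u: str, v: str, z: str) -> TripleSignature:
    """Classify the minimal topology induced by ordered nodes (u, v, z).

    Coincident nodes are allowed (two labels on one node have that node as
    their LCA).  The signature is deterministic in the slot order: slot a
    holds u, slot b holds v, slot c holds z.
    """
    try:
        ui = index.node_index[u]
        vi = index.node_index[v]
        zi = index.node_index[z]
    except KeyError as exc:
        raise KeyError(f"node {exc.args[0]!r} not in tree") from None
    code = int(index.signature_codes(np.array([ui]), np.array([vi]), np.array([zi]))[0])
    return TripleSignature.from_code(code)


@dataclass(frozen=True)
class ConfigMultiset:
    """Multiset of triple signatures with multiplicities.

    For labels a, b, c with occurrence counts n_a, n_b, n_c the total is
    n_a * n_b * n_c: one signature per ordered combination of occurrences.
    """

    counts: dict[TripleSignature, int]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("multiset counts must be positive")
        object.__setattr__(self, "total", sum(self.counts.values()))

    def intersection_size(self, other: "ConfigMultiset") -> int:
        return sum(
            min(c, other.counts.get(sig, 0)) for sig, c in self.counts.items()
        )


def label_triple_multiset(
    tree: LabeledTree, index: LCAIndex, a: str, b: str, c: str
) -> ConfigMultiset:
    """Configuration multiset of ordered label triple (a, b, c).

    Enumerates the full Cartesian product of the three labels' occurrence
    nodes (no deduplication of symmetric combinations).  A label absent from
    the tree yields the empty multiset (total 0) rather than an error, which
    is what the union-scoped score needs.
    """
    occ_a = tree.occurrences.get(a, ())
    occ_b = tree.occurrences.get(b, ())
    occ_c = tree.occurrences.get(c, ())
    if not (occ_a and occ_b and occ_c):
        return ConfigMultiset(counts={})
    ia = [index.node_index[n] for n in occ_a]
    ib = [index.node_index[n] for n in occ_b]
    ic = [index.node_index[n] for n in occ_c]
    u, v, z = np.meshgrid(ia, ib, ic, indexing="ij")
    codes = index.signature_codes(u.ravel(), v.ravel(), z.ravel())
    counter = Counter(int(c) for c in codes)
    return ConfigMultiset(
        counts={TripleSignature.from_code(code): n for code, n in counter.items()}
    )


# -- exhaustive shape enumeration ---------------------------------------------


def _rooted_trees(n: int) -> Iterator[tuple]:
    """All rooted unordered trees with exactly n nodes, as canonical nested
    tuples of child subtrees (sorted)."""
    if n == 1:
        yield ()
        return
    # partition n-1 nodes among an unordered multiset of child subtrees;
    # enforce non-increasing (size, shape) order to avoid duplicates
    def build(remaining: int, max_part: int, floor_shape) -> Iterator[tuple]:
        if remaining == 0:
            yield ()
            return
        for size in range(min(remaining, max_part), 0, -1):
            for shape in _rooted_trees(size):
                if size == max_part and floor_shape is not None and shape > floor_shape:
                    continue
                for rest in build(remaining - size, size, shape):
                    yield (shape,) + rest

    yield from build(n - 1, n - 1, None)


def _shape_to_tree(shape: tuple) -> LabeledTree:
    parent: dict[str, str] = {}
    labels: dict[str, frozenset[str]] = {}
    counter = itertools.count()

    def walk(sub: tuple, par: str | None) -> None:
        nid = f"n{next(counter):03d}"
        labels[nid] = frozenset([nid])
        if par is not None:
            parent[nid] = par
        for child in sub:
            walk(child, nid)

    walk(shape, None)
    return LabeledTree(parent=parent, root="n000", labels_of=labels)


def enumerate_shapes(max_nodes: int, allow_coincident: bool) -> set[int]:
    """Distinct minimal-topology configurations over all small trees.

    Exhaustively generates every rooted unordered tree with up to ``max_nodes``
    nodes and every node triple (with coincidences when ``allow_coincident``),
    then quotients the triple signatures by permutation of the three slots —
    configurations are defined for an *unordered* set of three labels.  Returns
    the set of canonical (permutation-minimal) signature codes.  Bounds below
    5 nodes yield a partial catalog; ``max_nodes >= 5`` recovers the five
    distinct-node configurations, and nine when coincidences are allowed.
    """
    if max_nodes < 1:
        raise ValueError("max_nodes must be >= 1")
    shapes: set[int] = set()
    for n in range(1, max_nodes + 1):
        for shape in _rooted_trees(n):
            tree = _shape_to_tree(shape)
            index = build_lca_index(tree)
            idxs = range(n)
            if allow_coincident:
                triples = itertools.combinations_with_replacement(idxs, 3)
            else:
                if n < 3:
                    continue
                triples = itertools.combinations(idxs, 3)
            trip = np.array(list(triples), dtype=np.int64)
            if trip.size == 0:
                continue
            canon = None
            for perm in itertools.permutations(range(3)):
                codes = index.signature_codes(
                    trip[:, perm[0]], trip[:, perm[1]], trip[:, perm[2]]
                )
                canon = codes if canon is None else np.minimum(canon, codes)
            shapes.update(int(c) for c in canon)
    return shapes
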