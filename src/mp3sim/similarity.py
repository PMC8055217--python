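"""The four MP3 similarity scores between multilabeled mutation trees.

For an unordered triple of distinct labels {a, b, c}, each tree contributes a
multiset of triple-topology configurations M_T(a, b, c) — one configuration
per ordered combination of the labels' occurrence nodes.  Across two trees the
triple contributes

    N(a, b, c) = |M_T1 ⊓ M_T2|        (multiset-intersection cardinality)
    D(a, b, c) = max(|M_T1|, |M_T2|)  (larger multiset cardinality)

and the scores are ratios of summed N over summed D:

    MP3∩  — over triples drawn from the shared label set λ(T1) ∩ λ(T2)
    MP3∪  — over triples drawn from the combined set λ(T1) ∪ λ(T2); a triple
            containing a label absent from a tree gets an empty multiset on
            that side, so it adds to the denominator only
    MP3_G — geometric mean sqrt(MP3∩ · MP3∪)
    MP3σ  — MP3∪ + σ(MP3∩) · min(MP3∩ − MP3∪, MP3∪), with σ the logistic
            sigmoid centered at 1/2 and steepness μ (default 10); the default
            reported score, biased toward MP3∩ for similar trees

Triples are unordered sets of three *distinct* labels; within a triple, the
slot order is the lexicographic label order in both trees, so the two
configuration multisets align label-by-label.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import LCAIndex, build_lca_index
from .treeio import LabeledTree

__all__ = [
    "SigmoidParams",
    "SimilarityResult",
    "InsufficientSharedLabelsError",
    "sigmoid",
    "triple_scores",
    "mp3_score",
    "shared_node_pairs",
    "similarity_matrix",
    "SCORE_MODES",
]

SCORE_MODES = ("sigmoid", "intersection", "union", "geometric")


class InsufficientSharedLabelsError(ValueError):
    """Fewer than three shared labels: the triple set for MP3∩ is empty."""


@dataclass(frozen=True)
class SigmoidParams:
    """Steepness μ of the logistic blend in MP3σ (μ = 10 by default)."""

    mu: float = 10.0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")


def sigmoid(x: float, params: SigmoidParams = SigmoidParams()) -> float:
    """Logistic sigmoid centered at 1/2: σ(x) = 1 / (1 + exp(-μ(x - 1/2)))."""
    return 1.0 / (1.0 + math.exp(-params.mu * (x - 0.5)))


@dataclass(frozen=True)
class SimilarityResult:
    """The four MP3 scores plus the exact integer per-triple aggregates.

    ``numerator_sum`` and ``denominator_sum`` are Σ N and Σ D over the shared
    triple set (MP3∩ = numerator_sum / denominator_sum);
    ``union_denominator_sum`` is Σ D over the combined triple set (the
    numerator of MP3∪ is the same Σ N, since a triple with a label missing
    from either tree has an empty multiset there and intersects to nothing).
    ``n_triples_considered`` counts triples contributing a nonzero D.
    """

    mp3_intersection: float
    mp3_union: float
    mp3_geometric: float
    mp3_sigmoid: float
    numerator_sum: int
    denominator_sum: int
    union_denominator_sum: int
    n_triples_considered: int

    def score(self, mode: str) -> float:
        if mode not in SCORE_MODES:
            raise ValueError(f"unknown mode {mode!r}; choose from {SCORE_MODES}")
        return getattr(self, f"mp3_{mode}")

    def __str__(self) -> str:
        return (
            f"MP3∩={self.mp3_intersection:.6f} MP3∪={self.mp3_union:.6f} "
            f"MP3_G={self.mp3_geometric:.6f} MP3σ={self.mp3_sigmoid:.6f}"
        )


def triple_scores(m1, m2) -> tuple[int, int]:
    """Per-triple numerator and denominator from two configuration multisets.

    N = Σ_signature min(count₁, count₂); D = max(total₁, total₂).
    """
    c1 = m1.counts if hasattr(m1, "counts") else dict(m1)
    c2 = m2.counts if hasattr(m2, "counts") else dict(m2)
    n = sum(min(c, c2.get(sig, 0)) for sig, c in c1.items())
    d = max(sum(c1.values()), sum(c2.values()))
    return n, d


def _occurrence_indices(tree: LabeledTree, index: LCAIndex, labels) -> list[np.ndarray]:
    return [
        np.array([index.node_index[n] for n in tree.occurrences.get(lab, ())],
                 dtype=np.int64)
        for lab in labels
    ]


def _poly_triple_counts(
    idx: LCAIndex, occ_u: np.ndarray, occ_v: np.ndarray, occ_z: np.ndarray
) -> Counter:
    u, v, z = np.meshgrid(occ_u, occ_v, occ_z, indexing="ij")
    return Counter(idx.signature_codes(u.ravel(), v.ravel(), z.ravel()).tolist())


def mp3_score(
    t1: LabeledTree,
    t2: LabeledTree,
    params: SigmoidParams = SigmoidParams(),
) -> SimilarityResult:
    """Compute all four MP3 scores between two trees.

    Raises :class:`InsufficientSharedLabelsError` when the trees share fewer
    than three labels, in which case MP3∩ is undefined.

    The common case — every label of a triple occurring exactly once in both
    trees — is evaluated in bulk with vectorized LCA queries; triples touching
    a poly-occurring label fall back to explicit enumeration of the ordered
    occurrence combinations.
    """
    shared = sorted(t1.label_set & t2.label_set)
    union = sorted(t1.label_set | t2.label_set)
    if len(shared) < 3:
        raise InsufficientSharedLabelsError(
            f"trees {t1.name!r} and {t2.name!r} share only {len(shared)} "
            "label(s); at least 3 are required"
        )
    idx1 = build_lca_index(t1)
    idx2 = build_lca_index(t2)

    # --- shared triples: Σ N and Σ D over I -----------------------------------
    occ1 = _occurrence_indices(t1, idx1, shared)
    occ2 = _occurrence_indices(t2, idx2, shared)
    n1 = np.array([len(o) for o in occ1], dtype=np.int64)
    n2 = np.array([len(o) for o in occ2], dtype=np.int64)

    trip = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(len(shared)), 3)),
        dtype=np.int64,
    ).reshape(-1, 3)
    singles1 = n1 == 1
    singles2 = n2 == 1
    fast = (
        singles1[trip[:, 0]] & singles1[trip[:, 1]] & singles1[trip[:, 2]]
        & singles2[trip[:, 0]] & singles2[trip[:, 1]] & singles2[trip[:, 2]]
    )
    node1 = np.array([o[0] if len(o) else -1 for o in occ1], dtype=np.int64)
    node2 = np.array([o[0] if len(o) else -1 for o in occ2], dtype=np.int64)

    ft = trip[fast]
    sum_n = 0
    sum_d = 0
    if len(ft):
        sig1 = idx1.signature_codes(node1[ft[:, 0]], node1[ft[:, 1]], node1[ft[:, 2]])
        sig2 = idx2.signature_codes(node2[ft[:, 0]], node2[ft[:, 1]], node2[ft[:, 2]])
        sum_n += int(np.count_nonzero(sig1 == sig2))
        sum_d += len(ft)
    for i, j, k in trip[~fast]:
        c1 = _poly_triple_counts(idx1, occ1[i], occ1[j], occ1[k])
        c2 = _poly_triple_counts(idx2, occ2[i], occ2[j], occ2[k])
        sum_n += sum(min(c, c2.get(sig, 0)) for sig, c in c1.items())
        sum_d += max(sum(c1.values()), sum(c2.values()))

    # --- union-only triples contribute D = max of the occurrence products ----
    # (N = 0: at least one label is absent from one tree, so that side's
    # multiset is empty; a triple absent from both sides has D = 0 and is
    # skipped entirely)
    cnt1 = np.array([len(t1.occurrences.get(lab, ())) for lab in union], dtype=np.int64)
    cnt2 = np.array([len(t2.occurrences.get(lab, ())) for lab in union], dtype=np.int64)
    in_both = (cnt1 > 0) & (cnt2 > 0)
    utrip = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(len(union)), 3)),
        dtype=np.int64,
    ).reshape(-1, 3)
    only = ~(in_both[utrip[:, 0]] & in_both[utrip[:, 1]] & in_both[utrip[:, 2]])
    ot = utrip[only]
    prod1 = cnt1[ot[:, 0]] * cnt1[ot[:, 1]] * cnt1[ot[:, 2]]
    prod2 = cnt2[ot[:, 0]] * cnt2[ot[:, 1]] * cnt2[ot[:, 2]]
    extra_d = np.maximum(prod1, prod2)
    union_d = sum_d + int(extra_d.sum())
    n_considered = len(trip) + int(np.count_nonzero(extra_d))

    if sum_d == 0 or union_d == 0:
        raise InsufficientSharedLabelsError(
            f"trees {t1.name!r} and {t2.name!r}: no triple realizes a "
            "configuration in either tree"
        )
    mp3_inter = sum_n / sum_d
    mp3_union = sum_n / union_d
    mp3_geom = math.sqrt(mp3_inter * mp3_union)
    mp3_sig = mp3_union + sigmoid(mp3_inter, params) * min(
        mp3_inter - mp3_union, mp3_union
    )
    return SimilarityResult(
        mp3_intersection=mp3_inter,
        mp3_union=mp3_union,
        mp3_geometric=mp3_geom,
        mp3_sigmoid=mp3_sig,
        numerator_sum=sum_n,
        denominator_sum=sum_d,
        union_denominator_sum=union_d,
        n_triples_considered=n_considered,
    )


def shared_node_pairs(t1: LabeledTree, t2: LabeledTree) -> tuple[int, int]:
    """Count label pairs co-located on one node in both trees.

    Returns ``(shared, candidate)``: *shared* is the number of unordered label
    pairs {p, q} with some node of t1 carrying both AND some node of t2
    carrying both; *candidate* counts pairs co-located in at least one node of
    either tree.  A deliberately naive statistic, useful as a sanity proxy
    when two trees disagree wildly under the full score.
    """

    def colocated(t: LabeledTree) -> set[frozenset[str]]:
        pairs: set[frozenset[str]] = set()
        for labs in t.labels_of.values():
            pairs.update(frozenset(p) for p in itertools.combinations(sorted(labs), 2))
        return pairs

    p1 = colocated(t1)
    p2 = colocated(t2)
    return len(p1 & p2), len(p1 | p2)


def similarity_matrix(
    trees: list[LabeledTree],
    params: SigmoidParams = SigmoidParams(),
    mode: str = "sigmoid",
) -> pd.DataFrame:
    """All-pairs score matrix (symmetric, unit diagonal) as a DataFrame.

    Pairs for which the score is undefined (insufficient shared labels) are
    recorded as NaN with a warning.  Row/column order follows the input list;
    duplicate tree names are disambiguated with a numeric suffix.
    """
    if len(trees) < 2:
        raise ValueError("similarity_matrix needs at least 2 trees")
    if mode not in SCORE_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {SCORE_MODES}")
    names: list[str] = []
    seen: Counter = Counter()
    for t in trees:
        seen[t.name] += 1
        names.append(t.name if seen[t.name] == 1 else f"{t.name}.{seen[t.name]}")
    mat = np.eye(len(trees))
    for i, j in itertools.combinations(range(len(trees)), 2):
        try:
            s = mp3_score(trees[i], trees[j], params).score(mode)
        except InsufficientSharedLabelsError as exc:
            warnings.warn(f"pair ({names[i]}, {names[j]}) skipped: {exc}", stacklevel=2)
            s = np.nan
        mat[i, j] = mat[j, i] = s
    return pd.DataFrame(mat, index=names, columns=names)
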