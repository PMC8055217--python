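"""Random tree perturbations for benchmark families.

Starting from a base tree, a configured number of actions is drawn i.i.d.
from a probability vector over five elementary perturbations:

label_swap
    two distinct labels exchange their full occurrence sets
label_removal
    one label is deleted from every node carrying it (an emptied node stays
    in place, unlabeled — topology changes are reserved to node operations)
label_duplication
    one label is added to a uniformly chosen node not already carrying it,
    creating a poly-occurrence
node_swap
    two distinct nodes exchange their label sets
node_removal
    one non-root node is deleted; its children reattach to its parent and its
    labels are discarded

All choices (operation, then its targets) flow through a single seeded
generator in a fixed order, so a (tree, config) pair reproduces its output
exactly.  An operation the current tree cannot support (e.g. node_removal on
a single node) is resampled, up to a retry cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .treeio import LabeledTree

__all__ = [
    "PerturbationConfig",
    "InapplicableOperation",
    "PerturbationError",
    "OPERATIONS",
    "perturb",
    "perturb_traced",
    "label_swap",
    "label_removal",
    "label_duplication",
    "node_swap",
    "node_removal",
]

OPERATIONS = (
    "label_swap",
    "label_removal",
    "label_duplication",
    "node_swap",
    "node_removal",
)

_RETRY_CAP = 100


class InapplicableOperation(RuntimeError):
    """The drawn operation cannot be applied to the current tree."""


class PerturbationError(RuntimeError):
    """No applicable operation could be drawn within the retry cap."""


@dataclass(frozen=True)
class PerturbationConfig:
    """Total number of actions, probability vector over the five operations
    (ordered as :data:`OPERATIONS`), and the generator seed."""

    n_ops: int
    probs: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ops < 0:
            raise ValueError("n_ops must be nonnegative")
        p = tuple(float(x) for x in self.probs)
        if len(p) != 5 or any(x < 0 for x in p):
            raise ValueError("probs must be 5 nonnegative reals")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError(f"probs must sum to 1, got {sum(p)}")
        object.__setattr__(self, "probs", p)


# mutable working copy: (parent dict, labels dict of sets)


def _thaw(tree: LabeledTree) -> tuple[dict, dict]:
    return dict(tree.parent), {n: set(s) for n, s in tree.labels_of.items()}


def _freeze(parent: dict, labels: dict, root: str, name: str) -> LabeledTree:
    return LabeledTree(
        parent=parent,
        root=root,
        labels_of={n: frozenset(s) for n, s in labels.items()},
        name=name,
    )


def _sorted_labels(labels: dict) -> list[str]:
    return sorted(set().union(*labels.values())) if labels else []


def _pick(rng: np.random.Generator, items: list):
    return items[int(rng.integers(len(items)))]


def label_swap(parent: dict, labels: dict, root: str, rng: np.random.Generator) -> None:
    """Exchange the occurrence sets of two uniformly chosen distinct labels."""
    labs = _sorted_labels(labels)
    if len(labs) < 2:
        raise InapplicableOperation("label_swap needs >= 2 distinct labels")
    i, j = rng.choice(len(labs), size=2, replace=False)
    a, b = labs[int(i)], labs[int(j)]
    for node, s in labels.items():
        has_a, has_b = a in s, b in s
        if has_a and not has_b:
            s.discard(a)
            s.add(b)
        elif has_b and not has_a:
            s.discard(b)
            s.add(a)


def label_removal(parent: dict, labels: dict, root: str, rng: np.random.Generator) -> None:
    """Delete one uniformly chosen label from every node carrying it."""
    labs = _sorted_labels(labels)
    if not labs:
        raise InapplicableOperation("label_removal needs >= 1 label")
    lab = _pick(rng, labs)
    for s in labels.values():
        s.discard(lab)


def label_duplication(parent: dict, labels: dict, root: str, rng: np.random.Generator) -> None:
    """Add one uniformly chosen label to a uniform node not already carrying it."""
    labs = _sorted_labels(labels)
    if not labs:
        raise InapplicableOperation("label_duplication needs >= 1 label")
    lab = _pick(rng, labs)
    eligible = sorted(n for n, s in labels.items() if lab not in s)
    if not eligible:
        raise InapplicableOperation(f"label {lab!r} already on every node")
    labels[_pick(rng, eligible)].add(lab)


def node_swap(parent: dict, labels: dict, root: str, rng: np.random.Generator) -> None:
    """Exchange the label sets of two uniformly chosen distinct nodes."""
    nodes = sorted(labels)
    if len(nodes) < 2:
        raise InapplicableOperation("node_swap needs >= 2 nodes")
    i, j = rng.choice(len(nodes), size=2, replace=False)
    a, b = nodes[int(i)], nodes[int(j)]
    labels[a], labels[b] = labels[b], labels[a]


def node_removal(parent: dict, labels: dict, root: str, rng: np.random.Generator) -> None:
    """Delete a uniform non-root node, reattaching its children to its parent;
    the removed node's labels are discarded."""
    candidates = sorted(n for n in labels if n != root)
    if not candidates:
        raise InapplicableOperation("node_removal needs a non-root node")
    victim = _pick(rng, candidates)
    up = parent[victim]
    for child, par in list(parent.items()):
        if par == victim:
            parent[child] = up
    del parent[victim]
    del labels[victim]


_OP_FUNCS = {
    "label_swap": label_swap,
    "label_removal": label_removal,
    "label_duplication": label_duplication,
    "node_swap": node_swap,
    "node_removal": node_removal,
}


def perturb_traced(
    tree: LabeledTree, config: PerturbationConfig
) -> tuple[LabeledTree, list[str]]:
    """Apply ``config.n_ops`` random perturbations; also return the realized
    operation sequence (for manifests and frequency checks)."""
    rng = np.random.default_rng(config.seed)
    parent, labels = _thaw(tree)
    applied: list[str] = []
    failures = 0
    while len(applied) < config.n_ops:
        op = OPERATIONS[int(rng.choice(5, p=config.probs))]
        try:
            _OP_FUNCS[op](parent, labels, tree.root, rng)
        except InapplicableOperation:
            failures += 1
            if failures > _RETRY_CAP:
                raise PerturbationError(
                    f"no applicable operation after {_RETRY_CAP} retries "
                    f"(tree too degenerate; last tried {op!r})"
                ) from None
            continue
        failures = 0
        applied.append(op)
    return _freeze(parent, labels, tree.root, f"{tree.name}_p{config.seed}"), applied


def perturb(tree: LabeledTree, config: PerturbationConfig) -> LabeledTree:
    """Apply ``config.n_ops`` random perturbations and return the new tree."""
    return perturb_traced(tree, config)[0]


def random_tree(
    n_nodes: int,
    seed: int,
    *,
    extra_labels_per_node: float = 0.0,
    name: str = "base",
) -> LabeledTree:
    """Random rooted base tree for benchmark families.

    Nodes are attached uniformly at random to an earlier node (a random
    recursive tree, which yields the broad, shallow topologies typical of
    inferred mutation trees).  Each node carries one unique label ``m<i>``;
    with ``extra_labels_per_node > 0``, a Poisson number of additional unique
    labels per node emulates multi-mutation clonal expansions.  Labels are
    unique across the tree, so poly-occurrences arise only through
    perturbation (label_duplication).
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    parent: dict[str, str] = {}
    labels: dict[str, frozenset[str]] = {}
    counter = 0
    for i in range(n_nodes):
        nid = f"v{i:03d}"
        if i > 0:
            parent[nid] = f"v{int(rng.integers(i)):03d}"
        labs = [f"m{counter}"]
        counter += 1
        if extra_labels_per_node > 0:
            for _ in range(int(rng.poisson(extra_labels_per_node))):
                labs.append(f"m{counter}")
                counter += 1
        labels[nid] = frozenset(labs)
    return LabeledTree(parent=parent, root="v000", labels_of=labels, name=name)
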