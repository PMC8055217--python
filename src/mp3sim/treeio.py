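"""Read, validate and write rooted multilabeled mutation trees.

A tumor phylogeny is modeled as a rooted, unordered tree in which every node
carries a (possibly empty) *set* of mutation labels and the same label may
occur on several nodes (a *poly-occurring* label, modeling recurrent gain or
loss of a mutation).  Trees are exchanged as GraphViz DOT digraphs, one tree
per file, with each node's ``label`` attribute holding a comma-separated
mutation list and edges oriented parent -> child.

Labels are opaque, case-sensitive strings compared by exact equality; a loss
event conventionally written with a trailing minus sign (``"a-"``) is simply a
distinct label.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "LabeledTree",
    "TreeParseError",
    "TreeStructureError",
    "TreeValidationError",
    "parse_dot",
    "read_dot",
    "write_dot",
    "validate",
]


class TreeParseError(ValueError):
    """The document is not a DOT digraph this dialect understands."""


class TreeStructureError(ValueError):
    """The edge set does not describe a single rooted tree."""


class TreeValidationError(ValueError):
    """Node/label content violates the multilabeled-tree invariants."""


@dataclass(frozen=True)
class LabeledTree:
    """A rooted unordered tree whose nodes carry sets of mutation labels.

    Parameters
    ----------
    parent
        Map from each non-root node id to its parent node id.
    root
        The unique parentless node.
    labels_of
        Map from node id to the (frozen) set of labels on that node.  Every
        node of the tree must appear as a key, even if unlabeled.
    name
        Optional display name (defaults to ``"tree"``); used by matrix output.

    Attributes derived on construction: ``occurrences`` inverts ``labels_of``
    (label -> sorted list of carrying nodes) and ``label_set`` is the union of
    all per-node label sets.
    """

    parent: Mapping[str, str]
    root: str
    labels_of: Mapping[str, frozenset[str]]
    name: str = "tree"
    occurrences: Mapping[str, tuple[str, ...]] = field(init=False, compare=False)
    label_set: frozenset[str] = field(init=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "parent", {str(k): str(v) for k, v in self.parent.items()}
        )
        object.__setattr__(
            self,
            "labels_of",
            {str(k): frozenset(v) for k, v in self.labels_of.items()},
        )
        problems = validate(self)
        if problems:
            raise TreeStructureError("; ".join(problems))
        occ: dict[str, list[str]] = {}
        for node in sorted(self.labels_of):
            for lab in self.labels_of[node]:
                occ.setdefault(lab, []).append(node)
        object.__setattr__(
            self, "occurrences", {lab: tuple(nodes) for lab, nodes in occ.items()}
        )
        object.__setattr__(self, "label_set", frozenset(occ))
        if any(not labs for labs in self.labels_of.values()):
            unlabeled = sorted(n for n, labs in self.labels_of.items() if not labs)
            warnings.warn(
                f"tree {self.name!r} has unlabeled node(s) {unlabeled}; they shape "
                "the topology but contribute no label occurrences",
                stacklevel=3,
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.labels_of))

    @property
    def n_nodes(self) -> int:
        return len(self.labels_of)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(c for c, p in self.parent.items() if p == node))

    def with_name(self, name: str) -> "LabeledTree":
        return LabeledTree(self.parent, self.root, self.labels_of, name=name)


def validate(tree: LabeledTree) -> list[str]:
    """Return a list of invariant violations (empty iff the tree is valid).

    Checks: a single root, acyclic and connected parent relation, every
    parent endpoint known, and labels at most once per node (guaranteed by the
    set representation but re-checked against ``occurrences`` when present).
    """
    problems: list[str] = []
    nodes = set(tree.labels_of)
    roots = nodes - set(tree.parent)
    if tree.root not in nodes:
        problems.append(f"root {tree.root!r} is not a node of the tree")
    if not roots:
        problems.append("no root: every node has a parent (cycle through all nodes)")
    elif roots != {tree.root}:
        problems.append(f"multiple roots: {sorted(roots)}")
    for child, par in tree.parent.items():
        if child not in nodes:
            problems.append(f"edge endpoint {child!r} has no node entry")
        if par not in nodes:
            problems.append(f"parent {par!r} of {child!r} has no node entry")
    # cycle / connectivity: walk up from every node
    for start in nodes:
        seen = {start}
        cur = start
        while cur in tree.parent:
            cur = tree.parent[cur]
            if cur in seen:
                problems.append(f"cycle reachable from node {start!r}")
                return problems
            seen.add(cur)
        if cur != tree.root and tree.root in nodes and not problems:
            problems.append(f"node {start!r} does not reach the root")
            return problems
    occ = getattr(tree, "occurrences", None)
    if occ is not None:
        derived: dict[str, set[str]] = {}
        for node, labs in tree.labels_of.items():
            for lab in labs:
                derived.setdefault(lab, set()).add(node)
        stated = {lab: set(ns) for lab, ns in occ.items()}
        if derived != stated:
            problems.append("occurrences is not the inverse of labels_of")
    return problems


# -- DOT dialect ---------------------------------------------------------------

_TOKEN = re.compile(
    r"""
    \s*(?:
        (?P<comment>//[^\n]*|\#[^\n]*|/\*.*?\*/)
      | (?P<quoted>"(?:[^"\\]|\\.)*")
      | (?P<arrow>->|--)
      | (?P<punct>[{}\[\];,=])
      | (?P<word>(?:(?!->|--)[^\s{}\[\];,=\"/])+|/)
    )""",
    re.VERBOSE | re.DOTALL,
)


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    text = text.rstrip()
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise TreeParseError(f"unreadable DOT near character {pos}")
        pos = m.end()
        if m.lastgroup == "comment":
            continue
        tokens.append(m.group(m.lastgroup))
    return tokens


def _unquote(tok: str) -> str:
    if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
        return re.sub(r"\\(.)", r"\1", tok[1:-1])
    return tok


def _split_labels(attr: str, node: str) -> frozenset[str]:
    parts = [p.strip() for p in attr.split(",")]
    parts = [p for p in parts if p]
    if len(parts) != len(set(parts)):
        dupes = sorted({p for p in parts if parts.count(p) > 1})
        raise TreeValidationError(
            f"node {node!r}: duplicate label(s) {dupes} within one node"
        )
    return frozenset(parts)


def parse_dot(text: str, name: str = "tree") -> LabeledTree:
    """Parse a DOT digraph into a :class:`LabeledTree`.

    The dialect is deliberately small: ``digraph`` only (an undirected
    ``graph`` is rejected because tumor phylogenies are rooted), node
    statements with a ``label="m1,m2,..."`` attribute, and ``a -> b`` edge
    statements read as parent -> child.  A node with no ``label`` attribute
    uses its own id as its single label; an explicitly empty ``label=""``
    yields an unlabeled node (permitted, with a warning).
    """
    tokens = _tokenize(text)
    if not tokens:
        raise TreeParseError("empty document")
    i = 0
    if tokens[i] == "strict":
        i += 1
    if tokens[i] != "digraph":
        if tokens[i] == "graph":
            raise TreeParseError("undirected 'graph' rejected: trees must be rooted")
        raise TreeParseError(f"expected 'digraph', found {tokens[i]!r}")
    i += 1
    if tokens[i] != "{":
        i += 1  # optional graph name
    if i >= len(tokens) or tokens[i] != "{":
        raise TreeParseError("expected '{' after digraph header")
    i += 1

    attrs: dict[str, str | None] = {}
    explicit: set[str] = set()
    edges: list[tuple[str, str]] = []
    order: list[str] = []

    def note(node: str) -> None:
        if node not in attrs:
            attrs[node] = None
            order.append(node)

    while i < len(tokens) and tokens[i] != "}":
        tok = tokens[i]
        if tok == ";":
            i += 1
            continue
        if tok in ("node", "edge", "graph") and i + 1 < len(tokens) and tokens[i + 1] == "[":
            # default-attribute statement: skip the bracket block
            i += 2
            while i < len(tokens) and tokens[i] != "]":
                i += 1
            i += 1
            continue
        ident = _unquote(tok)
        i += 1
        if i < len(tokens) and tokens[i] == "--":
            raise TreeParseError("undirected edge '--' rejected")
        if i < len(tokens) and tokens[i] == "->":
            note(ident)
            while i < len(tokens) and tokens[i] == "->":
                i += 1
                if i >= len(tokens):
                    raise TreeParseError("dangling '->'")
                child = _unquote(tokens[i])
                note(child)
                edges.append((ident, child))
                ident = child
                i += 1
            if i < len(tokens) and tokens[i] == "[":  # edge attrs: ignore
                while i < len(tokens) and tokens[i] != "]":
                    i += 1
                i += 1
        elif i < len(tokens) and tokens[i] == "[":
            note(ident)
            i += 1
            while i < len(tokens) and tokens[i] != "]":
                key = tokens[i]
                if i + 2 < len(tokens) and tokens[i + 1] == "=":
                    val = _unquote(tokens[i + 2])
                    if key == "label":
                        attrs[ident] = val
                        explicit.add(ident)
                    i += 3
                else:
                    i += 1
                if i < len(tokens) and tokens[i] == ",":
                    i += 1
            i += 1
        else:
            note(ident)
    if i >= len(tokens) or tokens[i] != "}":
        raise TreeParseError("missing closing '}'")

    if not order:
        raise TreeParseError("digraph declares no nodes")

    parent: dict[str, str] = {}
    for par, child in edges:
        if child in parent and parent[child] != par:
            raise TreeStructureError(
                f"node {child!r} has multiple parents: {parent[child]!r}, {par!r}"
            )
        parent[child] = par
    labels_of: dict[str, frozenset[str]] = {}
    for node in order:
        raw = attrs[node]
        if node in explicit:
            labels_of[node] = _split_labels(raw or "", node)
        else:
            labels_of[node] = frozenset([node])
    roots = [n for n in order if n not in parent]
    if not roots:
        raise TreeStructureError("no root: cycle through all nodes")
    if len(roots) > 1:
        raise TreeStructureError(f"multiple roots: {sorted(roots)}")
    return LabeledTree(parent=parent, root=roots[0], labels_of=labels_of, name=name)


def read_dot(path) -> LabeledTree:
    """Read one tree from a DOT file; the tree name is the file stem."""
    from pathlib import Path

    p = Path(path)
    return parse_dot(p.read_text(encoding="utf-8"), name=p.stem)


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_dot(tree: LabeledTree) -> str:
    """Serialize a tree to the DOT dialect :func:`parse_dot` reads.

    Node labels are written comma-separated in lexicographic order without
    spaces, so the output is canonical for a given tree; a round trip through
    :func:`parse_dot` reproduces an isomorphic tree with identical labels.
    """
    lines = [f"digraph {_quote(tree.name)} {{"]
    for node in tree.nodes:
        lab = ",".join(sorted(tree.labels_of[node]))
        lines.append(f"    {_quote(node)} [label={_quote(lab)}];")
    for child in sorted(tree.parent):
        lines.append(f"    {_quote(tree.parent[child])} -> {_quote(child)};")
    lines.append("}")
    return "\n".join(lines) + "\n"
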