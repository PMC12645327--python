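"""Rooted time trees with fossil (non-contemporaneous) tips.

Node ages are in years before present (BP); a branch's length is the age
difference between parent and child. Extant tips sit at age 0, fossil tips
(an extinct language, an archaeological loom) at age > 0. The module covers
newick/NEXUS I/O, patristic distances, depth normalisation, tip pruning,
MRCA ages, and majority-rule consensus with clade posterior supports.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

from .errors import (
    DegenerateInputError,
    FormatError,
    MissingReferenceError,
    ValidationError,
)


class Node:
    """A node of a rooted time tree."""

    __slots__ = ("parent", "children", "age", "label", "support")

    def __init__(
        self,
        age: float = 0.0,
        label: str | None = None,
        support: float | None = None,
    ) -> None:
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.age = float(age)
        self.label = label
        self.support = support

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> float:
        """Length of the branch above this node (0 for the root)."""
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "internal"
        return f"<Node {self.label or ''} {kind} age={self.age:.4g}>"


class TimeTree:
    """A rooted, binary-or-multifurcating tree with node ages in years BP."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self.validate()

    # -- construction ---------------------------------------------------- #

    @classmethod
    def from_newick(cls, text: str) -> "TimeTree":
        return parse_tree(text)

    def copy(self) -> "TimeTree":
        def rec(node: Node) -> Node:
            clone = Node(age=node.age, label=node.label, support=node.support)
            for child in node.children:
                clone.add_child(rec(child))
            return clone

        return TimeTree(rec(self.root))

    # -- validation and traversal ---------------------------------------- #

    def validate(self) -> None:
        labels = [t.label for t in self.tips()]
        if any(lab is None for lab in labels):
            raise ValidationError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for node in self.preorder():
            if node.parent is not None and node.parent.age < node.age - 1e-9:
                raise ValidationError(
                    f"negative branch length above {node.label or 'internal node'}: "
                    f"parent age {node.parent.age} < node age {node.age}"
                )

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length (root age minus youngest tip age)."""
        return self.root.age - min(t.age for t in self.tips())

    def find_tip(self, label: str) -> Node:
        for tip in self.tips():
            if tip.label == label:
                return tip
        raise MissingReferenceError(f"unknown tip label {label!r}")

    def total_branch_length(self) -> float:
        return sum(n.branch_length for n in self.preorder() if n.parent is not None)

    # -- queries ---------------------------------------------------------- #

    def mrca(self, labels: Iterable[str]) -> Node:
        labels = list(labels)
        if not labels:
            raise MissingReferenceError("empty taxon set has no MRCA")
        nodes = [self.find_tip(lab) for lab in labels]
        # walk the first tip's ancestor path, take the shallowest covering node
        path: list[Node] = []
        node: Node | None = nodes[0]
        while node is not None:
            path.append(node)
            node = node.parent
        ancestors = {id(n): i for i, n in enumerate(path)}
        best = 0
        for other in nodes[1:]:
            node = other
            while id(node) not in ancestors:
                node = node.parent  # type: ignore[assignment]
                if node is None:  # pragma: no cover - single-rooted tree
                    raise ValidationError("disconnected tree")
            best = max(best, ancestors[id(node)])
        return path[best]

    def clades(self) -> dict[frozenset[str], Node]:
        """Map each internal node's tip-label set to the node (root included)."""
        below: dict[int, frozenset[str]] = {}
        out: dict[frozenset[str], Node] = {}
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = frozenset([node.label])  # type: ignore[list-item]
            else:
                clade = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = clade
                out[clade] = node
        return out

    # -- newick ----------------------------------------------------------- #

    def to_newick(self, *, include_support: bool = False, precision: int = 12) -> str:
        def rec(node: Node) -> str:
            if node.is_tip:
                body = _quote_newick(node.label)  # type: ignore[arg-type]
            else:
                body = "(" + ",".join(rec(c) for c in node.children) + ")"
                if include_support and node.support is not None:
                    body += f"[&support={node.support:.6g}]"
            if node.parent is not None:
                body += f":{node.branch_length:.{precision}g}"
            return body

        return rec(self.root) + ";"


def _quote_newick(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`<>"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------- #
# Parsing
# ---------------------------------------------------------------------- #


def parse_tree(text: str) -> TimeTree:
    """Parse a newick string with branch lengths into a :class:`TimeTree`.

    Node ages are reconstructed from root-to-tip depths: each tip is assigned
    age = (max root-to-tip depth) - (its own depth), so contemporaneous tips
    sit at age 0 and shorter tip paths become fossil tips with positive ages.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:
        raise FormatError(f"could not parse newick: {exc}") from exc
    return _from_dendropy(dtree)


def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    depths: dict[int, float] = {}

    def build(dnode, depth: float) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or dnode.taxon.label is None:
                raise FormatError("unlabelled tip in tree")
            node = Node(label=dnode.taxon.label)
        else:
            node = Node()
        depths[id(node)] = depth
        for dchild in dnode.child_nodes():
            length = dchild.edge.length
            if length is None:
                raise FormatError(
                    "missing branch length in newick (all branches need lengths)"
                )
            if length < 0:
                raise FormatError(f"negative branch length {length}")
            node.add_child(build(dchild, depth + float(length)))
        return node

    root = build(dtree.seed_node, 0.0)
    max_depth = max(
        depths[id(n)] for n in _iter_nodes(root) if not n.children
    )
    for node in _iter_nodes(root):
        node.age = max_depth - depths[id(node)]
        if abs(node.age) < 1e-12:
            node.age = 0.0
    return TimeTree(root)


def _iter_nodes(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(node.children)


def read_trees(path: str, schema: str = "auto") -> list[TimeTree]:
    """Read a list of trees from a NEXUS TREES block (translate table
    supported) or a newick file with one tree per line; ``schema="auto"``
    sniffs the leading #NEXUS marker."""
    if schema == "auto":
        with open(path) as fh:
            head = fh.read(64).lstrip()
        schema = "nexus" if head.upper().startswith("#NEXUS") else "newick"
    try:
        tl = dendropy.TreeList.get(path=path, schema=schema)
    except Exception as exc:
        raise FormatError(f"could not parse tree file {path}: {exc}") from exc
    return [_from_dendropy(t) for t in tl]


def write_trees(trees: Sequence[TimeTree], path: str, schema: str = "nexus") -> None:
    """Write trees as a NEXUS TREES block or plain newick lines."""
    if schema == "newick":
        with open(path, "w") as fh:
            for t in trees:
                fh.write(t.to_newick() + "\n")
        return
    if schema != "nexus":
        raise FormatError(f"unknown tree schema {schema!r}")
    labels = trees[0].tip_labels if trees else []
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TREES;\n")
        fh.write("  TRANSLATE\n")
        index = {lab: i + 1 for i, lab in enumerate(sorted(labels))}
        fh.write(
            ",\n".join(f"    {i} {_quote_newick(lab)}" for lab, i in index.items())
        )
        fh.write(";\n")
        for k, t in enumerate(trees):
            renamed = t.copy()
            for tip in renamed.tips():
                tip.label = str(index[tip.label])
            fh.write(f"  TREE tree_{k} = {renamed.to_newick()}\n")
        fh.write("END;\n")


# ---------------------------------------------------------------------- #
# Metric operations
# ---------------------------------------------------------------------- #


def patristic_matrix(t: TimeTree, order: Sequence[str]) -> np.ndarray:
    """Pairwise path-length (patristic) distances among the named tips.

    d(i, j) = sum of branch lengths from tip i up to the MRCA and back down
    to tip j = (2 * age(MRCA) - age(i) - age(j)).
    """
    tips = {lab: t.find_tip(lab) for lab in order}
    # root-to-node ancestor maps for MRCA lookups
    n = len(order)
    D = np.zeros((n, n))
    paths: dict[str, list[Node]] = {}
    for lab, tip in tips.items():
        path = []
        node: Node | None = tip
        while node is not None:
            path.append(node)
            node = node.parent
        paths[lab] = path
    for i in range(n):
        anc = {id(node): node for node in paths[order[i]]}
        for j in range(i + 1, n):
            node = tips[order[j]]
            while id(node) not in anc:
                node = node.parent  # type: ignore[assignment]
            mrca = anc[id(node)]
            D[i, j] = D[j, i] = (
                2.0 * mrca.age - tips[order[i]].age - tips[order[j]].age
            )
    return D


def normalise_by_depth(t: TimeTree) -> TimeTree:
    """Scale all branch lengths by 1/depth so the deepest root-to-tip path is 1.

    Used before averaging distances over posterior samples so deep trees do
    not dominate.
    """
    depth = t.depth
    if depth <= 0:
        raise DegenerateInputError("cannot depth-normalise a zero-depth tree")
    out = t.copy()
    youngest = min(tip.age for tip in out.tips())
    for node in out.preorder():
        node.age = (node.age - youngest) / depth
    return out


def prune_tips(t: TimeTree, keep: Iterable[str]) -> TimeTree:
    """Induced tree on a subset of tips.

    Unary internal nodes are suppressed (their branch lengths merge), so all
    pairwise patristic distances among kept tips are preserved exactly.
    """
    keep = set(keep)
    if len(keep) < 2:
        raise DegenerateInputError("need at least 2 tips to prune to")
    tip_labels = set(t.tip_labels)
    unknown = keep - tip_labels
    if unknown:
        raise MissingReferenceError(f"unknown tip label(s): {sorted(unknown)}")

    def rec(node: Node) -> Node | None:
        if node.is_tip:
            if node.label in keep:
                return Node(age=node.age, label=node.label)
            return None
        kept_children = [c for c in (rec(ch) for ch in node.children) if c is not None]
        if not kept_children:
            return None
        if len(kept_children) == 1:
            return kept_children[0]  # suppress unary node; ages carry the metric
        new = Node(age=node.age, support=node.support)
        for c in kept_children:
            new.add_child(c)
        return new

    new_root = rec(t.root)
    assert new_root is not None
    return TimeTree(new_root)


def mrca_age(t: TimeTree, tips: Iterable[str]) -> float:
    """Age (years BP) of the most recent common ancestor of the named tips."""
    return t.mrca(tips).age


# ---------------------------------------------------------------------- #
# Majority-rule consensus
# ---------------------------------------------------------------------- #


def majority_consensus(
    trees: Sequence[TimeTree], threshold: float = 0.5
) -> TimeTree:
    """Majority-rule consensus of a posterior tree sample.

    Contains exactly the clades occurring in a fraction >= ``threshold`` of
    the trees (the threshold is inclusive: a clade in exactly half the sample
    is kept at threshold 0.5). Internal nodes carry clade support in per
    cent; a consensus node's age is the mean MRCA age of its clade over the
    trees that contain it, so the consensus is generally not ultrametric.
    Incompatible clades at identical frequency (possible only below 0.5 or at
    exactly 0.5) are resolved deterministically in favour of the
    lexicographically smallest tip set.
    """
    if len(trees) == 0:
        raise ValidationError("empty tree collection")
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    tip_set = frozenset(trees[0].tip_labels)
    counts: dict[frozenset[str], int] = {}
    age_sums: dict[frozenset[str], float] = {}
    tip_age_sums: dict[str, float] = {lab: 0.0 for lab in tip_set}
    for t in trees:
        if frozenset(t.tip_labels) != tip_set:
            raise ValidationError("trees have mismatched tip sets")
        for clade, node in t.clades().items():
            counts[clade] = counts.get(clade, 0) + 1
            age_sums[clade] = age_sums.get(clade, 0.0) + node.age
        for tip in t.tips():
            tip_age_sums[tip.label] += tip.age  # type: ignore[index]

    n = len(trees)
    candidates = [
        clade
        for clade, c in counts.items()
        if c / n >= threshold - 1e-12 and len(clade) > 1
    ]
    candidates.sort(key=lambda c: (-counts[c], sorted(c)))
    accepted: list[frozenset[str]] = [tip_set] if tip_set not in candidates else []
    for clade in candidates:
        if all(_compatible(clade, other) for other in accepted):
            accepted.append(clade)

    # build the tree: nest accepted clades by containment
    accepted.sort(key=len, reverse=True)
    nodes: dict[frozenset[str], Node] = {}
    for clade in accepted:
        freq = counts.get(clade, n) / n
        age = age_sums.get(clade, 0.0) / counts[clade] if clade in counts else 0.0
        node = Node(age=age, support=100.0 * freq)
        if clade not in counts:  # root clade absent only if trees disagree at root
            node.age = max(age_sums[c] / counts[c] for c in counts if len(c) > 1)
            node.support = 100.0
        nodes[clade] = node
    for lab in tip_set:
        nodes[frozenset([lab])] = Node(age=tip_age_sums[lab] / n, label=lab)

    ordered = sorted(nodes, key=len, reverse=True)
    for clade in ordered:
        if clade == tip_set:
            continue
        parent = min(
            (c for c in ordered if len(c) > len(clade) and clade < c),
            key=len,
        )
        nodes[parent].add_child(nodes[clade])
    root = nodes[tip_set]
    # mean ages of nested clades can invert when computed over different
    # subsets of trees; clamp children to their parent's age
    for clade in ordered:
        node = nodes[clade]
        if node.parent is not None and node.age > node.parent.age:
            node.age = node.parent.age
    return TimeTree(root)


def _compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    return a <= b or b <= a or not (a & b)
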