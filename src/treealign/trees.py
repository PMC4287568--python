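"""Labeled rooted binary guide-trees: enumeration, canonical forms, counting.

A guide-tree dictates the order in which a progressive aligner merges
sequences and profiles.  Profile alignment is a symmetric operation, so
swapping the two children of any node does not change the resulting
alignment; trees are therefore represented, counted and deduplicated *up
to child swaps*.

Counting facts used throughout:

* the number of distinct labeled rooted binary trees on ``n`` leaves is
  the double factorial ``(2n-3)!!``;
* the number of unlabeled shapes is the Wedderburn-Etherington number;
* a shape with symmetry degree ``s`` (internal nodes whose two child
  subtrees are isomorphic) admits ``n!/2^s`` distinct labelings, because
  the automorphism group of the shape has order ``2^s``.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Optional, Sequence, Union

import numpy as np


class TreeError(ValueError):
    """Raised for invalid tree structures or arguments."""


# --------------------------------------------------------------------------
# representation
# --------------------------------------------------------------------------

class Node:
    """A tree node: either a labeled leaf or an internal node with children.

    ``length`` is the length of the edge above the node (``None`` when the
    tree carries no branch lengths, ignored on the root).
    """

    __slots__ = ("label", "children", "length")

    def __init__(
        self,
        label: Optional[str] = None,
        children: Sequence["Node"] = (),
        length: Optional[float] = None,
    ) -> None:
        self.label = label
        self.children: list[Node] = list(children)
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(
            self.label,
            [c.copy() for c in self.children],
            self.length,
        )

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> Iterator["Node"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({_newick(self)})"


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,'\"]")


def _format_label(label: str) -> str:
    if label == "" or _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick(node: Node, with_lengths: bool = False) -> str:
    if node.is_leaf:
        s = _format_label(node.label if node.label is not None else "")
    else:
        s = "(" + ",".join(_newick(c, with_lengths) for c in node.children) + ")"
        if node.label is not None:
            s += _format_label(node.label)
    if with_lengths and node.length is not None:
        s += f":{node.length:.10g}"
    return s


class GuideTree:
    """A strictly binary rooted tree with unique leaf labels.

    This is the object every guide-tree producer in the package returns
    and the progressive aligner consumes.
    """

    def __init__(self, root: Node, validate: bool = True) -> None:
        self.root = root
        if validate:
            self.validate()

    def validate(self) -> None:
        labels = []
        for node in self.root.postorder():
            if node.is_leaf:
                if node.label is None:
                    raise TreeError("leaf without a label")
                labels.append(node.label)
            elif len(node.children) != 2:
                raise TreeError(
                    f"internal node with {len(node.children)} children; "
                    "guide-trees must be strictly binary"
                )
        if len(labels) < 2:
            raise TreeError("a guide-tree needs at least 2 leaves")
        if len(set(labels)) != len(labels):
            raise TreeError("leaf labels must be unique")

    # -- basic queries ----------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.root.leaves()]

    def label_set(self) -> frozenset:
        return frozenset(self.leaf_labels())

    def copy(self) -> "GuideTree":
        return GuideTree(self.root.copy(), validate=False)

    # -- serialisation ----------------------------------------------------

    def newick(self, with_lengths: Optional[bool] = None) -> str:
        if with_lengths is None:
            with_lengths = any(
                n.length is not None
                for n in self.root.postorder()
                if n is not self.root
            )
        return _newick(self.root, with_lengths) + ";"

    def canonical_newick(self) -> str:
        """Child-swap-invariant labeled form (no branch lengths).

        Children are ordered by the smallest leaf label they contain, so
        two trees equal up to child swaps serialise identically.  Used for
        deduplication and as a cache key.
        """
        _, s = _canonical_labeled(self.root)
        return s + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GuideTree({self.newick()!r})"

    # -- construction helpers --------------------------------------------

    @classmethod
    def from_nested(cls, nested) -> "GuideTree":
        """Build from nested tuples/lists of labels, e.g. ``(("a","b"),"c")``."""

        def build(obj) -> Node:
            if isinstance(obj, (tuple, list)):
                return Node(children=[build(o) for o in obj])
            return Node(label=str(obj))

        return cls(build(nested))


def _canonical_labeled(node: Node) -> tuple[str, str]:
    """Return (smallest contained label, canonical string) for a subtree."""
    if node.is_leaf:
        lab = _format_label(node.label)
        return node.label, lab
    parts = sorted(_canonical_labeled(c) for c in node.children)
    return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"


def _unlabeled_form(node: Node) -> tuple[int, str]:
    """Return (leaf count, canonical unlabeled string) for a subtree.

    Children are ordered by (leaf count, string), making the form
    invariant under child swaps and relabeling.
    """
    if node.is_leaf:
        return 1, "L"
    parts = sorted(_unlabeled_form(c) for c in node.children)
    count = sum(p[0] for p in parts)
    return count, "(" + ",".join(p[1] for p in parts) + ")"


def _symmetry_degree(node: Node) -> int:
    if node.is_leaf:
        return 0
    s = sum(_symmetry_degree(c) for c in node.children)
    if len(node.children) == 2:
        if _unlabeled_form(node.children[0]) == _unlabeled_form(node.children[1]):
            s += 1
    return s


# --------------------------------------------------------------------------
# shapes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeShape:
    """A canonical unlabeled rooted binary topology.

    ``symmetry_degree`` counts internal nodes whose two child subtrees are
    isomorphic; ``shape_id`` is the index in the deterministic enumeration
    order for ``n_leaves``.
    """

    form: str
    n_leaves: int
    symmetry_degree: int
    shape_id: int

    def to_tree(self, labels: Optional[Sequence[str]] = None) -> GuideTree:
        """Materialise the shape, assigning ``labels`` to leaves left-to-right."""
        if labels is None:
            labels = [f"t{i + 1}" for i in range(self.n_leaves)]
        labels = list(labels)
        if len(labels) != self.n_leaves:
            raise TreeError(
                f"shape has {self.n_leaves} leaves but {len(labels)} labels given"
            )
        it = iter(labels)
        root = _parse_form(self.form, it)
        return GuideTree(root, validate=self.n_leaves >= 2)


def _parse_form(form: str, labels: Iterator[str]) -> Node:
    pos = 0

    def parse() -> Node:
        nonlocal pos
        if form[pos] == "L":
            pos += 1
            return Node(label=next(labels))
        assert form[pos] == "("
        pos += 1
        left = parse()
        assert form[pos] == ","
        pos += 1
        right = parse()
        assert form[pos] == ")"
        pos += 1
        return Node(children=[left, right])

    node = parse()
    if pos != len(form):
        raise TreeError(f"malformed shape string {form!r}")
    return node


@lru_cache(maxsize=None)
def _shape_forms(n: int) -> tuple[tuple[str, int], ...]:
    """All (canonical form, symmetry degree) pairs on n leaves, sorted."""
    if n == 1:
        return (("L", 0),)
    out = []
    for a in range(1, n // 2 + 1):
        b = n - a
        if a < b:
            for fa, sa in _shape_forms(a):
                for fb, sb in _shape_forms(b):
                    out.append((f"({fa},{fb})", sa + sb))
        else:  # a == b: unordered pairs of equal-size subshapes
            forms = _shape_forms(a)
            for i, (fa, sa) in enumerate(forms):
                for fb, sb in forms[i:]:
                    lo, hi = sorted((fa, fb))
                    out.append((f"({lo},{hi})", sa + sb + (1 if fa == fb else 0)))
    return tuple(sorted(out))


def enumerate_shapes(n: int) -> list[TreeShape]:
    """All unlabeled rooted binary topologies on ``n`` leaves.

    The list length is the Wedderburn-Etherington number (2, 3, 6, 11, 23
    for n = 4..8; 10,905 for n = 16).
    """
    if n < 1:
        raise TreeError(f"n must be >= 1, got {n}")
    return [
        TreeShape(form=f, n_leaves=n, symmetry_degree=s, shape_id=i)
        for i, (f, s) in enumerate(_shape_forms(n))
    ]


@lru_cache(maxsize=None)
def _shape_index(n: int) -> dict:
    return {shape.form: shape for shape in enumerate_shapes(n)}


def shape_of(tree: GuideTree) -> TreeShape:
    """The canonical unlabeled topology of a tree.

    Invariant under relabeling and under swapping the children of any node.
    """
    n, form = _unlabeled_form(tree.root)
    return _shape_index(n)[form]


# --------------------------------------------------------------------------
# counting and enumeration
# --------------------------------------------------------------------------

def count_labeled_trees(n: int) -> int:
    """Number of distinct labeled rooted binary trees on ``n`` leaves.

    Equals the double factorial ``(2n-3)!!``; exact integer arithmetic
    (e.g. 135,135 for n = 8 and about 6.2e15 for n = 16).
    """
    if n < 2:
        raise TreeError(f"n must be >= 2, got {n}")
    result = 1
    for m in range(1, 2 * n - 2, 2):
        result *= m
    return result


def count_distinct_labelings(shape: TreeShape) -> int:
    """Distinct labelings of a shape: ``n!/2^s`` (exact integer).

    Each of the ``n!`` leaf assignments coincides with ``2^s`` others
    under the shape's child-swap automorphisms.
    """
    return math.factorial(shape.n_leaves) // (2 ** shape.symmetry_degree)


MAX_ENUMERATION_LEAVES = 16


def enumerate_labeled_trees(labels: Sequence[str]) -> Iterator[GuideTree]:
    """Yield every distinct labeled rooted binary tree on ``labels`` once.

    Uses recursive leaf insertion: the k-th label is attached on each of
    the ``2k-3`` possible positions (above the root, or on the edge above
    any non-root node) of every tree on the first ``k-1`` labels.  This is
    duplicate-free by construction and yields ``(2n-3)!!`` trees in a
    deterministic order.
    """
    labels = [str(l) for l in labels]
    if len(set(labels)) != len(labels):
        raise TreeError("labels must be unique")
    if not 2 <= len(labels) <= MAX_ENUMERATION_LEAVES:
        raise TreeError(
            f"exhaustive enumeration supports 2..{MAX_ENUMERATION_LEAVES} "
            f"labels, got {len(labels)}"
        )

    def gen(k: int) -> Iterator[Node]:
        if k == 2:
            yield Node(children=[Node(label=labels[0]), Node(label=labels[1])])
            return
        new_label = labels[k - 1]
        for base in gen(k - 1):
            # position 0: new root above the old one
            yield Node(children=[base.copy(), Node(label=new_label)])
            # positions 1..2k-4: the edge above each non-root node (preorder)
            n_positions = sum(1 for _ in base.preorder()) - 1
            for idx in range(n_positions):
                tree = base.copy()
                target, parent = _nth_nonroot_preorder(tree, idx)
                where = parent.children.index(target)
                parent.children[where] = Node(
                    children=[target, Node(label=new_label)]
                )
                yield tree

    for root in gen(len(labels)):
        yield GuideTree(root, validate=False)


def _nth_nonroot_preorder(root: Node, idx: int) -> tuple[Node, Node]:
    """The idx-th non-root node in preorder, with its parent."""
    counter = -1
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        if parent is not None:
            counter += 1
            if counter == idx:
                return node, parent
        # push children reversed so they pop in left-to-right order
        for child in reversed(node.children):
            stack.append((child, node))
    raise IndexError(idx)


def random_labeling(
    shape: TreeShape,
    labels: Sequence[str],
    seed: Union[int, np.random.Generator],
) -> GuideTree:
    """A uniformly random distinct labeling of ``shape``.

    A uniform permutation of the labels is written onto the shape's leaf
    slots; since every distinct labeling corresponds to exactly ``2^s``
    permutations, the draw is uniform over the ``n!/2^s`` distinct trees.
    """
    labels = [str(l) for l in labels]
    if len(labels) != shape.n_leaves:
        raise TreeError(
            f"shape has {shape.n_leaves} leaves but {len(labels)} labels given"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = [labels[i] for i in rng.permutation(len(labels))]
    return shape.to_tree(perm)
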