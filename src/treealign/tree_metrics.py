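"""Tree balance indices, rooted Robinson-Foulds distance, midpoint rooting.

Balance is the degree to which a rooted tree splits its leaves evenly at
every node: perfectly balanced trees (possible when the leaf count is a
power of two) sit at one extreme, perfectly chained (pectinate) trees at
the other.  Several indices quantify intermediate trees and disagree on
their ranking, so all the common ones are reported together.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .trees import GuideTree, Node, TreeError


@dataclass(frozen=True)
class BalanceReport:
    """The four balance indices of one rooted binary tree.

    * ``sackin``: sum of leaf depths (in edges). Minimal for the perfectly
      balanced shape, maximal for the perfectly chained one.
    * ``colless``: sum over internal nodes of the absolute difference in
      leaf counts of the two child subtrees. Zero iff perfectly balanced
      at every node.
    * ``inverse_max``: Shao-Sokal B1 — sum over non-root internal nodes of
      the reciprocal of the maximum edge count down to any descendant leaf.
    * ``depth_entropy``: Shannon entropy (bits) of the leaf-depth
      frequency distribution.
    """

    sackin: int
    colless: int
    inverse_max: float
    depth_entropy: float


def balance_indices(tree: GuideTree) -> BalanceReport:
    """Compute all four balance indices; branch lengths are ignored."""
    root = tree.root
    leaf_counts: dict[int, int] = {}
    max_down: dict[int, int] = {}  # max edges from node down to a leaf
    colless = 0
    inverse_max = 0.0
    for node in root.postorder():
        if node.is_leaf:
            leaf_counts[id(node)] = 1
            max_down[id(node)] = 0
        else:
            left, right = node.children
            leaf_counts[id(node)] = leaf_counts[id(left)] + leaf_counts[id(right)]
            max_down[id(node)] = 1 + max(max_down[id(left)], max_down[id(right)])
            colless += abs(leaf_counts[id(left)] - leaf_counts[id(right)])
            if node is not root:
                inverse_max += 1.0 / max_down[id(node)]

    depths: list[int] = []

    def collect(node: Node, depth: int) -> None:
        if node.is_leaf:
            depths.append(depth)
        else:
            for child in node.children:
                collect(child, depth + 1)

    collect(root, 0)
    sackin = sum(depths)
    counts = np.bincount(depths)
    p = counts[counts > 0] / len(depths)
    depth_entropy = float(-(p * np.log2(p)).sum())
    return BalanceReport(
        sackin=sackin,
        colless=colless,
        inverse_max=inverse_max,
        depth_entropy=depth_entropy,
    )


# --------------------------------------------------------------------------
# rooted Robinson-Foulds
# --------------------------------------------------------------------------

def _clades(tree: GuideTree) -> set[frozenset]:
    """Non-trivial clades: leaf sets of internal nodes other than the root."""
    out = set()
    leaf_sets: dict[int, frozenset] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            leaf_sets[id(node)] = frozenset([node.label])
        else:
            s = frozenset().union(*(leaf_sets[id(c)] for c in node.children))
            leaf_sets[id(node)] = s
            if node is not tree.root:
                out.add(s)
    return out


def rooted_rf_distance(t1: GuideTree, t2: GuideTree) -> int:
    """Rooted Robinson-Foulds distance: symmetric difference of clade sets.

    Zero for trees that are isomorphic and label preserving; the maximum
    for two rooted binary trees on ``n`` leaves is ``2(n - 2)`` (12 when
    n = 8), attained by trees sharing no non-trivial clade.
    """
    if t1.label_set() != t2.label_set():
        raise TreeError("trees must share the same leaf-label set")
    return len(_clades(t1) ^ _clades(t2))


# --------------------------------------------------------------------------
# midpoint rooting
# --------------------------------------------------------------------------

def midpoint_root(tree: Union[GuideTree, Node]) -> GuideTree:
    """Root a branch-length-bearing tree at the midpoint of its diameter.

    The input is interpreted as unrooted: an existing root of degree two
    is suppressed.  The new root is placed halfway along the longest
    leaf-to-leaf path, so the two maximal root-to-leaf distances (one per
    root subtree) are equal.  Ties for the longest path are broken by the
    lexicographically smallest leaf-label pair.
    """
    root = tree.root if isinstance(tree, GuideTree) else tree

    # Build the undirected weighted graph.  Node ids are assigned in
    # preorder so the construction is traversal-order independent given
    # the same topology.
    nodes = list(root.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    labels = {index[id(n)]: n.label for n in nodes if n.is_leaf}
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(nodes))}
    for node in nodes:
        for child in node.children:
            if child.length is None:
                raise TreeError("midpoint rooting requires branch lengths on every edge")
            if child.length < 0:
                raise TreeError("negative branch length")
            u, v = index[id(node)], index[id(child)]
            adj[u].append((v, float(child.length)))
            adj[v].append((u, float(child.length)))

    leaves = sorted(labels, key=lambda i: labels[i])
    if len(leaves) < 3:
        raise TreeError("midpoint rooting needs at least 3 leaves")

    def distances_from(src: int) -> dict[int, float]:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    best = None  # (distance, (label_a, label_b), leaf_a, leaf_b)
    for a in leaves:
        dist = distances_from(a)
        for b in leaves:
            if b == a:
                continue
            pair = tuple(sorted((labels[a], labels[b])))
            cand = (dist[b], pair)
            if best is None or cand[0] > best[0] + 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 and pair < best[1]
            ):
                best = (cand[0], pair, a if labels[a] == pair[0] else b,
                        b if labels[a] == pair[0] else a)
    diameter, _, end_a, end_b = best

    # Path from end_a to end_b.
    parent: dict[int, tuple[int, float]] = {}
    stack = [end_a]
    seen = {end_a}
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = (u, w)
                stack.append(v)
    path = [end_b]
    while path[-1] != end_a:
        path.append(parent[path[-1]][0])
    path.reverse()  # end_a .. end_b

    # Locate the midpoint along the path, walking from end_a.
    half = diameter / 2.0
    cum = 0.0
    edge_weights = {}
    for u, nbrs in adj.items():
        for v, w in nbrs:
            edge_weights[(u, v)] = w
    split_u = split_v = None
    offset = 0.0
    for u, v in zip(path, path[1:]):
        w = edge_weights[(u, v)]
        if cum + w >= half - 1e-12:
            split_u, split_v, offset = u, v, min(max(half - cum, 0.0), w)
            break
        cum += w
    if split_u is None:  # zero-diameter degenerate tree
        split_u, split_v = path[0], path[1]
        offset = 0.0

    # Re-root: a fresh node in the middle of edge (split_u, split_v).
    def orient(i: int, came_from: int, edge_len: float) -> Node:
        kids = [
            orient(j, i, w) for j, w in sorted(adj[i]) if j != came_from
        ]
        if labels.get(i) is not None and not kids:
            return Node(label=labels[i], length=edge_len)
        return Node(children=kids, length=edge_len)

    left = orient(split_u, split_v, offset)
    w = edge_weights[(split_u, split_v)]
    right = orient(split_v, split_u, w - offset)
    new_root = Node(children=[left, right])

    _suppress_unary(new_root)
    return GuideTree(new_root)


def _suppress_unary(node: Node) -> None:
    """Merge nodes with a single child into the edge below them."""
    for i, child in enumerate(node.children):
        _suppress_unary(child)
        if len(child.children) == 1:
            grand = child.children[0]
            grand.length = (grand.length or 0.0) + (child.length or 0.0)
            node.children[i] = grand


# --------------------------------------------------------------------------
# branch-length variability
# --------------------------------------------------------------------------

def branch_length_variability(tree: GuideTree) -> float:
    """Coefficient of variation (population sd / mean) of all branch lengths.

    Scale-free: multiplying every branch by a constant leaves it
    unchanged.  Defined as 0 when all lengths are zero.
    """
    lengths = []
    for node in tree.root.postorder():
        if node is tree.root:
            continue
        if node.length is None:
            raise TreeError("branch length variability requires branch lengths")
        lengths.append(float(node.length))
    if len(lengths) < 2:
        raise TreeError("need at least 2 edges")
    arr = np.asarray(lengths)
    mean = arr.mean()
    if mean == 0.0:
        return 0.0
    return float(arr.std() / mean)
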