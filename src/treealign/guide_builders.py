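"""Guide-tree construction: distance-based clustering and chained trees.

Six distance-matrix schemes (single, complete, mean/centroid, Ward,
UPGMA, neighbour joining) plus perfectly chained trees populated by
descriptor-based orderings (length, hydrophobic moment, isoelectric
point, highest/lowest identity; ascending or descending, with optional
secondary keys).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .aligner import AlignParams, DEFAULT_PARAMS
from .descriptors import (
    family_descriptors,
    ktuple_distance,
    percent_identity,
)
from .family import ProteinFamily, SequenceRecord
from .tree_metrics import midpoint_root
from .trees import GuideTree, Node


class BuilderError(ValueError):
    """Raised for invalid guide-tree builder inputs."""


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric non-negative distance matrix over named sequences."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if v.shape != (n, n):
            raise BuilderError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise BuilderError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise BuilderError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise BuilderError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)


def build_distance_matrix(
    family: Union[ProteinFamily, list[SequenceRecord]],
    method: str = "ktuple",
    k: int = 1,
    params: AlignParams = DEFAULT_PARAMS,
) -> DistanceMatrix:
    """Pairwise distances among family members.

    ``ktuple``: alignment-free k-mer distance of the unaligned sequences.
    ``aligned_identity``: ``1 - identity/100`` from optimal pairwise
    alignments under the aligner's parameters.
    """
    records = family.sequences if isinstance(family, ProteinFamily) else list(family)
    if len(records) < 2:
        raise BuilderError("need at least 2 sequences")
    if method not in ("ktuple", "aligned_identity"):
        raise BuilderError(f"unknown distance method {method!r}")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if method == "ktuple":
                val = ktuple_distance(records[i], records[j], k)
            else:
                val = 1.0 - percent_identity(records[i], records[j], params) / 100.0
            d[i, j] = d[j, i] = val
    return DistanceMatrix(ids=tuple(r.id for r in records), values=d)


#: Map from scheme name to the scipy linkage method implementing it.
#: "mean" is centroid (UPGMC) linkage — merging by distance between
#: cluster centroids — which is distinct from UPGMA (group average).
CLUSTER_SCHEMES = {
    "single": "single",
    "complete": "complete",
    "mean": "centroid",
    "ward": "ward",
    "upgma": "average",
}


def cluster_guide_tree(D: DistanceMatrix, scheme: str) -> GuideTree:
    """Agglomerative guide-tree under one of the five linkage schemes.

    Node heights are half the merge distance (so an ultrametric input is
    reproduced exactly by UPGMA); branch lengths are differences of
    heights, clamped at zero where a scheme produces inversions.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    if scheme not in CLUSTER_SCHEMES:
        raise BuilderError(
            f"unknown clustering scheme {scheme!r}; "
            f"expected one of {sorted(CLUSTER_SCHEMES)}"
        )
    if D.n < 2:
        raise BuilderError("need at least 2 sequences")
    if D.n == 2:
        a, b = D.ids
        h = D.values[0, 1] / 2.0
        return GuideTree(Node(children=[Node(label=a, length=h),
                                        Node(label=b, length=h)]))
    Z = linkage(squareform(D.values, checks=False), method=CLUSTER_SCHEMES[scheme])
    nodes = [Node(label=i) for i in D.ids]
    heights = [0.0] * len(nodes)
    for left, right, dist, _ in Z:
        li, ri = int(left), int(right)
        h = float(dist) / 2.0
        for ci in (li, ri):
            nodes[ci].length = max(h - heights[ci], 0.0)
        nodes.append(Node(children=[nodes[li], nodes[ri]]))
        heights.append(h)
    return GuideTree(nodes[-1])


def nj_guide_tree(D: DistanceMatrix) -> GuideTree:
    """Neighbour-joining tree, midpoint rooted.

    Standard Q-matrix neighbour joining produces an unrooted additive
    tree; negative branch-length estimates are clamped to zero and the
    tree is rooted at the midpoint of its diameter.
    """
    if D.n < 3:
        raise BuilderError("neighbour joining needs at least 3 sequences")
    import skbio

    dm = skbio.DistanceMatrix(D.values, ids=list(D.ids))
    nj_tree = skbio.tree.nj(dm)

    def convert(skb_node) -> Node:
        length = skb_node.length
        length = 0.0 if length is None else max(float(length), 0.0)
        if skb_node.is_tip():
            return Node(label=skb_node.name, length=length)
        return Node(children=[convert(c) for c in skb_node.children], length=length)

    unrooted = convert(nj_tree)
    unrooted.length = None
    return midpoint_root(unrooted)


def chained_tree_from_order(ordered_ids: Sequence[str]) -> GuideTree:
    """The perfectly chained tree ``(((id1,id2),id3),...,idn)``.

    The first two ids form the deepest cherry and are therefore aligned
    first; each subsequent id joins the growing profile in order.
    """
    ids = [str(i) for i in ordered_ids]
    if len(ids) < 2:
        raise BuilderError("need at least 2 ids")
    if len(set(ids)) != len(ids):
        raise BuilderError("ids must be unique")
    node = Node(children=[Node(label=ids[0]), Node(label=ids[1])])
    for label in ids[2:]:
        node = Node(children=[node, Node(label=label)])
    return GuideTree(node)


ORDERING_KEYS = ("len", "hm", "hml", "ip", "ipl", "hi", "lo")


@dataclass(frozen=True)
class OrderingSpec:
    """A sort specification for populating chained trees.

    ``key`` is one of len/hm/hml/ip/ipl/hi/lo, ``direction`` is ``asc``
    or ``desc``; an optional ``secondary`` spec breaks ties (remaining
    ties keep input order — the sort is stable).
    """

    key: str
    direction: str = "asc"
    secondary: Optional["OrderingSpec"] = None

    def __post_init__(self) -> None:
        key = self.key.lower()
        object.__setattr__(self, "key", key)
        if key not in ORDERING_KEYS:
            raise BuilderError(
                f"unknown ordering key {self.key!r}; expected one of {ORDERING_KEYS}"
            )
        if self.direction not in ("asc", "desc"):
            raise BuilderError(f"direction must be 'asc' or 'desc', got {self.direction!r}")
        if self.secondary is not None and self.secondary.secondary is not None:
            raise BuilderError("ordering specs chain at most one secondary key")

    @classmethod
    def parse(cls, text: str) -> "OrderingSpec":
        """Parse short forms like ``"len/a"``, ``"hi/d"``, ``"len/a+ip/d"``."""
        parts = text.split("+")
        if len(parts) > 2:
            raise BuilderError("ordering specs chain at most one secondary key")
        specs = []
        for part in parts:
            try:
                key, direction = part.split("/")
            except ValueError:
                raise BuilderError(f"malformed ordering spec {part!r}")
            specs.append((key, {"a": "asc", "d": "desc"}.get(direction, direction)))
        secondary = cls(*specs[1]) if len(specs) == 2 else None
        return cls(specs[0][0], specs[0][1], secondary)

    def short(self) -> str:
        s = f"{self.key}/{self.direction[0]}"
        if self.secondary is not None:
            s += "+" + self.secondary.short()
        return s


def order_by_descriptors(
    family: Union[ProteinFamily, list[SequenceRecord]],
    spec: Union[OrderingSpec, str],
    params: AlignParams = DEFAULT_PARAMS,
    descriptors: Optional[dict] = None,
) -> list[str]:
    """Sequence ids sorted by a descriptor spec (stable; ties keep input order)."""
    if isinstance(spec, str):
        spec = OrderingSpec.parse(spec)
    records = family.sequences if isinstance(family, ProteinFamily) else list(family)
    if descriptors is None:
        descriptors = family_descriptors(records, params)

    def sort_key(rec: SequenceRecord):
        keys = []
        s = spec
        while s is not None:
            val = getattr(descriptors[rec.id], "length" if s.key == "len" else s.key)
            keys.append(-val if s.direction == "desc" else val)
            s = s.secondary
        return tuple(keys)

    return [rec.id for rec in sorted(records, key=sort_key)]


def chained_tree_by_descriptors(
    family: Union[ProteinFamily, list[SequenceRecord]],
    spec: Union[OrderingSpec, str],
    params: AlignParams = DEFAULT_PARAMS,
    descriptors: Optional[dict] = None,
) -> GuideTree:
    """Convenience: chained tree populated by a descriptor ordering."""
    return chained_tree_from_order(
        order_by_descriptors(family, spec, params, descriptors)
    )
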