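"""Guide-tree exploration: exhaustive or sampled scoring of every tree.

For a family of n sequences this aligns under each of the (2n-3)!!
distinct labeled guide-trees (or a random sample of labelings per
shape for larger n), scores each alignment against the reference, and
offers the summaries the analysis needs: the optimum and how many trees
attain it, minimum RF distance from the optimum set to a reference tree,
and per-topology score distributions ordered by imbalance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .aligner import AlignParams, DEFAULT_PARAMS, progressive_align
from .family import ProteinFamily
from .guide_builders import (
    build_distance_matrix,
    chained_tree_by_descriptors,
    chained_tree_from_order,
    cluster_guide_tree,
    nj_guide_tree,
)
from .scoring import NoCoreColumnsError, sp_score, tc_score
from .tree_metrics import balance_indices, rooted_rf_distance
from .trees import (
    GuideTree,
    TreeShape,
    count_distinct_labelings,
    enumerate_labeled_trees,
    enumerate_shapes,
    random_labeling,
    shape_of,
)


class ExplorationError(ValueError):
    """Raised for invalid exploration requests."""


RECORD_COLUMNS = ["tree", "shape_id", "tc", "sp"]


@dataclass
class ScoreTable:
    """One record per evaluated guide-tree for one family."""

    family: str
    records: pd.DataFrame  # columns: tree (canonical newick), shape_id, tc, sp
    engine: str = ""

    def __post_init__(self) -> None:
        if list(self.records.columns) != RECORD_COLUMNS:
            self.records = self.records[RECORD_COLUMNS]
        if self.records["tree"].duplicated().any():
            raise ExplorationError("duplicate trees in score table")

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path], family: str = "",
                 engine: str = "") -> "ScoreTable":
        return cls(family=family, engine=engine,
                   records=pd.read_csv(path, sep="\t"))


#: Profiles cached only for subtrees up to this many leaves; larger
#: subtrees are too numerous to keep for n = 7-8 exhaustive runs.
CACHE_MAX_LEAVES = 4


class _BoundedCache(dict):
    """Subtree-profile cache that ignores subtrees above the size bound.

    Keys are canonical subtree newicks; a subtree on m leaves has m-1
    commas.
    """

    def __setitem__(self, key: str, value) -> None:
        if key.count(",") < CACHE_MAX_LEAVES:
            super().__setitem__(key, value)

EXHAUSTIVE_WARN_LEAVES = 8
CHECKPOINT_EVERY = 1000


def _score_trees(
    family: ProteinFamily,
    trees: Iterable[GuideTree],
    params: AlignParams,
    checkpoint: Optional[Path] = None,
) -> pd.DataFrame:
    if family.reference is None:
        raise ExplorationError(f"family {family.name!r} has no reference alignment")
    if family.reference.n_core_columns == 0:
        raise NoCoreColumnsError(
            f"family {family.name!r} has no core columns; flagged, not scored"
        )
    done: dict[str, tuple] = {}
    if checkpoint is not None and Path(checkpoint).exists():
        prev = pd.read_csv(checkpoint, sep="\t")
        done = {r.tree: (r.tree, r.shape_id, r.tc, r.sp)
                for r in prev.itertuples()}
    cache = _BoundedCache()
    rows = list(done.values())
    fresh: list[tuple] = []

    def flush() -> None:
        if checkpoint is not None and fresh:
            header = not Path(checkpoint).exists()
            pd.DataFrame(fresh, columns=RECORD_COLUMNS).to_csv(
                checkpoint, sep="\t", index=False, mode="a", header=header
            )
            fresh.clear()

    for tree in trees:
        key = tree.canonical_newick()
        if key in done:
            continue
        aln = progressive_align(family, tree, params, cache=cache)
        rec = (key, shape_of(tree).shape_id,
               tc_score(aln, family.reference), sp_score(aln, family.reference))
        rows.append(rec)
        fresh.append(rec)
        done[key] = rec
        if len(fresh) >= CHECKPOINT_EVERY:
            flush()
    flush()
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def exhaustive_exploration(
    family: ProteinFamily,
    params: AlignParams = DEFAULT_PARAMS,
    checkpoint: Optional[Union[str, Path]] = None,
) -> ScoreTable:
    """Score every distinct labeled guide-tree for a family.

    One record per tree from the duplicate-free enumeration, i.e.
    ``(2n-3)!!`` records (15 for n=4, 105 for n=5, 135,135 for n=8).
    ``checkpoint`` makes long runs resumable without duplicating records.
    """
    n = family.n_sequences
    if n > EXHAUSTIVE_WARN_LEAVES:
        warnings.warn(
            f"exhaustive exploration of {n} sequences evaluates "
            f"(2n-3)!! trees; consider sample_exploration", stacklevel=2,
        )
    records = _score_trees(
        family, enumerate_labeled_trees(family.ids), params,
        checkpoint=Path(checkpoint) if checkpoint else None,
    )
    return ScoreTable(family=family.name, records=records,
                      engine=params.fingerprint())


def find_best(table: ScoreTable) -> tuple[float, set, int]:
    """The optimum TC score, the set of trees attaining it, and its size."""
    if len(table) == 0:
        raise ExplorationError("empty score table")
    best_tc = float(table.records["tc"].max())
    best = set(table.records.loc[table.records["tc"] == best_tc, "tree"])
    return best_tc, best, len(best)


def min_rf_to(best_trees: Iterable[Union[str, GuideTree]],
              reference_tree: GuideTree) -> int:
    """Minimum rooted RF distance from a reference tree to a set of trees.

    Used to ask how far e.g. an estimated phylogeny is from the nearest
    optimum guide-tree when several trees tie for the optimum.
    """
    from .io import parse_newick

    best = None
    for tree in best_trees:
        if isinstance(tree, str):
            tree = parse_newick(tree)
        d = rooted_rf_distance(tree, reference_tree)
        best = d if best is None else min(best, d)
        if best == 0:
            return 0
    if best is None:
        raise ExplorationError("empty tree set")
    return best


def summarize_by_shape(table: ScoreTable) -> pd.DataFrame:
    """Per-topology TC summaries, ordered by increasing imbalance.

    Shapes are ordered by Colless index (ties by Sackin, then shape id);
    the first row is the most balanced shape present, the last the
    perfectly chained one.  Quartiles are linear-interpolation
    percentiles over all records of the shape.
    """
    if len(table) == 0:
        raise ExplorationError("empty score table")
    n_leaves = table.records["tree"].iloc[0].count(",") + 1
    shapes = {s.shape_id: s for s in enumerate_shapes(n_leaves)}
    rows = []
    for shape_id, group in table.records.groupby("shape_id"):
        shape = shapes[int(shape_id)]
        bal = balance_indices(shape.to_tree())
        tc = group["tc"].to_numpy()
        rows.append({
            "shape_id": int(shape_id),
            "form": shape.form,
            "colless": bal.colless,
            "sackin": bal.sackin,
            "n_trees": len(group),
            "tc_min": float(tc.min()),
            "tc_q1": float(np.percentile(tc, 25)),
            "tc_median": float(np.percentile(tc, 50)),
            "tc_q3": float(np.percentile(tc, 75)),
            "tc_max": float(tc.max()),
            "tc_mean": float(tc.mean()),
        })
    rows.sort(key=lambda r: (r["colless"], r["sackin"], r["shape_id"]))
    return pd.DataFrame(rows)


def sample_exploration(
    family: ProteinFamily,
    shapes: Optional[Sequence[TreeShape]] = None,
    labelings_per_shape: int = 100,
    seed: int = 0,
    params: AlignParams = DEFAULT_PARAMS,
) -> ScoreTable:
    """Score sampled labelings of selected shapes (for n beyond exhaustive).

    For each shape, distinct labelings are drawn uniformly without
    replacement; a request exceeding the shape's ``n!/2^s`` distinct
    labelings is capped (with a warning) at exhaustive coverage.
    """
    if labelings_per_shape < 1:
        raise ExplorationError("labelings_per_shape must be >= 1")
    n = family.n_sequences
    if shapes is None:
        shapes = enumerate_shapes(n)
    rng = np.random.default_rng(seed)
    ids = family.ids
    trees: list[GuideTree] = []
    for shape in shapes:
        if shape.n_leaves != n:
            raise ExplorationError(
                f"shape on {shape.n_leaves} leaves does not fit a family "
                f"of {n} sequences"
            )
        available = count_distinct_labelings(shape)
        target = labelings_per_shape
        if target > available:
            warnings.warn(
                f"shape {shape.shape_id}: only {available} distinct "
                f"labelings exist; capping", stacklevel=2,
            )
            target = available
        seen: dict[str, GuideTree] = {}
        attempts = 0
        max_attempts = 200 * target + 1000
        while len(seen) < target and attempts < max_attempts:
            tree = random_labeling(shape, ids, rng)
            seen.setdefault(tree.canonical_newick(), tree)
            attempts += 1
        if len(seen) < target:  # pragma: no cover - astronomically unlikely
            raise ExplorationError("sampling failed to reach the target")
        trees.extend(seen.values())
    records = _score_trees(family, trees, params)
    return ScoreTable(family=family.name, records=records,
                      engine=params.fingerprint())


# --------------------------------------------------------------------------
# named guide-tree strategies
# --------------------------------------------------------------------------

def _clustering_strategy(scheme: str) -> Callable:
    def build(family: ProteinFamily, params: AlignParams) -> GuideTree:
        D = build_distance_matrix(family, method="aligned_identity", params=params)
        return cluster_guide_tree(D, scheme)

    return build


def _nj_strategy(family: ProteinFamily, params: AlignParams) -> GuideTree:
    D = build_distance_matrix(family, method="aligned_identity", params=params)
    return nj_guide_tree(D)


def _true_tree_strategy(family: ProteinFamily, params: AlignParams) -> GuideTree:
    if family.true_tree is None:
        raise ExplorationError(f"family {family.name!r} has no true tree")
    return family.true_tree


def _chained_random_strategy(family: ProteinFamily, params: AlignParams,
                             seed: int = 0) -> GuideTree:
    rng = np.random.default_rng(seed)
    ids = list(family.ids)
    order = [ids[i] for i in rng.permutation(len(ids))]
    return chained_tree_from_order(order)


BUILTIN_STRATEGIES = {
    **{scheme: _clustering_strategy(scheme)
       for scheme in ("single", "complete", "mean", "ward", "upgma")},
    "nj": _nj_strategy,
    "true_tree": _true_tree_strategy,
    "chained_random": _chained_random_strategy,
}


def resolve_strategy(name: str) -> Callable:
    """Look up a named strategy; ``chained:<spec>`` builds ordered chains."""
    if name in BUILTIN_STRATEGIES:
        return BUILTIN_STRATEGIES[name]
    if name.startswith("chained:"):
        spec = name.split(":", 1)[1]

        def build(family: ProteinFamily, params: AlignParams) -> GuideTree:
            return chained_tree_by_descriptors(family, spec, params)

        return build
    raise ExplorationError(f"unknown strategy {name!r}")


def compare_strategies(
    families: Sequence[ProteinFamily],
    strategies: Union[Sequence[str], dict],
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean TC per strategy over families, with per-family detail.

    ``strategies`` is a list of names (see :func:`resolve_strategy`) or a
    mapping name -> callable(family, params) -> GuideTree.  A strategy
    failing on a family is recorded as missing; means are over the
    available families.  Returns (summary, detail).
    """
    if not isinstance(strategies, dict):
        strategies = {name: resolve_strategy(name) for name in strategies}
    detail_rows = []
    for fam in families:
        for name, build in strategies.items():
            try:
                tree = build(fam, params)
                aln = progressive_align(fam, tree, params)
                tc = tc_score(aln, fam.reference)
                sp = sp_score(aln, fam.reference)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                warnings.warn(
                    f"strategy {name!r} failed on family {fam.name!r}: {exc}",
                    stacklevel=2,
                )
                tc = sp = np.nan
            detail_rows.append(
                {"family": fam.name, "strategy": name, "tc": tc, "sp": sp}
            )
    detail = pd.DataFrame(detail_rows)
    summary = (
        detail.groupby("strategy", sort=False)[["tc", "sp"]]
        .mean()
        .reset_index()
        .rename(columns={"tc": "mean_tc", "sp": "mean_sp"})
    )
    summary["n_families"] = [
        int(detail[detail["strategy"] == s]["tc"].notna().sum())
        for s in summary["strategy"]
    ]
    summary["best"] = summary["mean_tc"] == summary["mean_tc"].max()
    return summary, detail
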