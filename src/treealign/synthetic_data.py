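"""Simulated protein families with known true alignments.

The generator evolves a root sequence down a random (or supplied) tree
with per-site substitutions and geometric-length indels, keeping exact
column bookkeeping so the *true* multiple alignment is known.  It is
built to emulate the statistical envelope of structure-derived benchmark
families — 4-16 homologous sequences of length roughly 30-900 with
average pairwise identities spanning roughly 15-80% — so that every
downstream stage (descriptors, guide-tree builders, aligner, scoring,
exploration) can be exercised without any external data.

The model is deliberately simple: substitutions replace a residue by a
draw from a single background composition (no rate matrix, no site-rate
variation), and insertions/deletions are equiprobable with geometric
lengths at uniform positions.  Core columns of the simulated reference
are the gapless columns — the analogue of columns where every structure
agrees.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Union

import numpy as np

from .aligner import GAP, Profile
from .family import AMINO_ACIDS, ProteinFamily, SequenceRecord
from .scoring import ReferenceAlignment
from .trees import GuideTree, Node


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


class CalibrationError(SimulationError):
    """Raised when a target identity cannot be reached.

    Carries ``closest`` — the best mean identity achieved.
    """

    def __init__(self, message: str, closest: float) -> None:
        super().__init__(message)
        self.closest = closest


#: Background amino-acid composition (Robinson & Robinson style frequencies).
BACKGROUND_FREQUENCIES = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064,
}

_BG_RESIDUES = np.array(list(BACKGROUND_FREQUENCIES))
_BG_P = np.array(list(BACKGROUND_FREQUENCIES.values()))
_BG_P = _BG_P / _BG_P.sum()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated family.

    Defaults describe a mid-range benchmark family: 8 sequences of root
    length 150 evolving under substitution rate 1 /site/unit-length with
    occasional short indels, on a random join tree with exponential
    branch lengths of mean 0.25 (divergence units).
    """

    n_sequences: int = 8
    root_length: int = 150
    substitution_rate: float = 1.0
    indel_rate: float = 0.02
    indel_length_mean: float = 1.8
    branch_length_mean: float = 0.25
    tree_source: Union[str, GuideTree, None] = None  # None/"random" or a tree
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise SimulationError("need at least 2 sequences")
        if self.root_length < 1:
            raise SimulationError("root length must be >= 1")
        for name in ("substitution_rate", "indel_rate", "branch_length_mean"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.indel_length_mean < 1:
            raise SimulationError("indel_length_mean must be >= 1")


@dataclass
class SimulatedFamily(ProteinFamily):
    """A :class:`ProteinFamily` carrying the generating configuration."""

    config: Optional[SimulationConfig] = None

    @property
    def true_alignment(self) -> ReferenceAlignment:
        return self.reference


def _random_tree(labels: list[str], mean: float, rng: np.random.Generator) -> GuideTree:
    """Random join order with exponential branch lengths (mean ``mean``)."""
    lineages = [Node(label=l) for l in labels]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        right = lineages.pop(j)
        left = lineages.pop(i)
        for child in (left, right):
            child.length = float(rng.exponential(mean)) if mean > 0 else 0.0
        lineages.append(Node(children=[left, right]))
    return GuideTree(lineages[0])


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Evolve one family; the same seed always yields identical output."""
    rng = np.random.default_rng(config.seed)
    labels = [f"seq{i + 1}" for i in range(config.n_sequences)]

    if config.tree_source is None or config.tree_source == "random":
        tree = _random_tree(labels, config.branch_length_mean, rng)
    elif isinstance(config.tree_source, GuideTree):
        tree = config.tree_source.copy()
    else:
        from .io import parse_newick

        tree = parse_newick(config.tree_source)
    if set(tree.leaf_labels()) != set(labels):
        labels = tree.leaf_labels()

    # Root sequence: iid draws from the background composition.  Each
    # site carries a persistent column id; insertions mint fresh ids that
    # are spliced into the global column order next to their anchor.
    next_col = config.root_length
    columns: list[int] = list(range(config.root_length))
    root_seq = list(zip(
        range(config.root_length),
        rng.choice(_BG_RESIDUES, size=config.root_length, p=_BG_P),
    ))

    leaf_seqs: dict[str, list] = {}

    def evolve(seq: list, node: Node) -> None:
        nonlocal next_col
        if node.is_leaf:
            leaf_seqs[node.label] = seq
            return
        for child in node.children:
            t = float(child.length) if child.length is not None else 1.0
            child_seq = _evolve_branch(seq, t)
            evolve(child_seq, child)

    def _evolve_branch(seq: list, t: float) -> list:
        nonlocal next_col
        seq = list(seq)
        # substitutions: per-site Poisson events; a hit redraws from the
        # background, so the observed difference rate is slightly lower.
        p_sub = 1.0 - math.exp(-config.substitution_rate * t)
        hits = np.flatnonzero(rng.random(len(seq)) < p_sub)
        if hits.size:
            new_res = rng.choice(_BG_RESIDUES, size=hits.size, p=_BG_P)
            for pos, res in zip(hits, new_res):
                seq[pos] = (seq[pos][0], res)
        # indels: Poisson number of events over the branch
        n_events = rng.poisson(config.indel_rate * t * len(seq))
        for _ in range(n_events):
            length = int(rng.geometric(1.0 / config.indel_length_mean))
            if rng.random() < 0.5 and len(seq) > length:  # deletion
                pos = int(rng.integers(0, len(seq) - length + 1))
                del seq[pos:pos + length]
            else:  # insertion
                pos = int(rng.integers(0, len(seq) + 1))
                fresh = list(range(next_col, next_col + length))
                next_col += length
                if pos == 0:
                    anchor = columns.index(seq[0][0]) if seq else 0
                else:
                    anchor = columns.index(seq[pos - 1][0]) + 1
                columns[anchor:anchor] = fresh
                residues = rng.choice(_BG_RESIDUES, size=length, p=_BG_P)
                seq[pos:pos] = list(zip(fresh, residues))
        return seq

    evolve(root_seq, tree.root)

    # Project every leaf onto the global column order, dropping columns
    # that no surviving sequence retains.
    used = set()
    for seq in leaf_seqs.values():
        used.update(col for col, _ in seq)
    kept = [c for c in columns if c in used]
    col_pos = {c: i for i, c in enumerate(kept)}
    rows = []
    for label in labels:
        chars = [GAP] * len(kept)
        for col, res in leaf_seqs[label]:
            chars[col_pos[col]] = res
        rows.append((label, "".join(chars)))
    alignment = Profile(rows)
    reference = ReferenceAlignment.from_profile(alignment)  # core = gapless

    sequences = [SequenceRecord(id=label, residues=alignment.degapped(label))
                 for label in labels]
    fam = SimulatedFamily(
        name=f"sim-n{config.n_sequences}-s{config.seed}",
        sequences=sequences,
        reference=reference,
        true_tree=tree,
        config=config,
    )
    ident = mean_pairwise_identity(fam)
    if ident < 5.0:
        warnings.warn(
            f"simulated family has mean identity {ident:.1f}% (<5%); "
            "rates may be degenerate", stacklevel=2,
        )
    return fam


def mean_pairwise_identity(family: ProteinFamily) -> float:
    """Mean percent identity over all pairs, read off the true alignment.

    Identity of a pair = matches / columns where both hold a residue.
    """
    aln = family.reference.alignment
    rows = [np.frombuffer(row.encode(), dtype=np.uint8) for _, row in aln.rows]
    gap = ord(GAP)
    vals = []
    for a, b in combinations(rows, 2):
        both = (a != gap) & (b != gap)
        n = int(both.sum())
        vals.append(100.0 * float((a[both] == b[both]).sum()) / n if n else 0.0)
    return float(np.mean(vals))


def calibrate_identity(
    target_identity: float,
    config: SimulationConfig,
    replicates: int = 100,
    tolerance: float = 3.0,
    max_iterations: int = 30,
) -> SimulationConfig:
    """Scale branch lengths until simulated families hit a target identity.

    Bisection on a multiplier of ``branch_length_mean``: at each step the
    mean pairwise identity over ``replicates`` fresh seeds is compared to
    ``target_identity`` (percent); success is within ``tolerance`` points.
    """
    if not 10.0 <= target_identity <= 95.0:
        raise SimulationError(
            f"target identity must be in [10, 95], got {target_identity}"
        )
    rng = np.random.default_rng(config.seed)
    seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=replicates)]

    def mean_identity(scale: float) -> float:
        vals = []
        for seed in seeds:
            cfg = replace(
                config,
                branch_length_mean=config.branch_length_mean * scale,
                seed=seed,
            )
            vals.append(mean_pairwise_identity(simulate_family(cfg)))
        return float(np.mean(vals))

    lo, hi = 1e-3, 1.0
    f_hi = mean_identity(hi)
    closest = (abs(f_hi - target_identity), hi, f_hi)
    # expand until the bracket straddles the target (identity decreases
    # with divergence, so f(lo) > target > f(hi) is wanted)
    for _ in range(12):
        if f_hi <= target_identity:
            break
        hi *= 2.0
        f_hi = mean_identity(hi)
        closest = min(closest, (abs(f_hi - target_identity), hi, f_hi))
    f_lo = mean_identity(lo)
    closest = min(closest, (abs(f_lo - target_identity), lo, f_lo))
    if f_lo < target_identity or f_hi > target_identity:
        raise CalibrationError(
            f"cannot reach {target_identity}% (closest achieved "
            f"{closest[2]:.1f}%)", closest=closest[2],
        )
    for _ in range(max_iterations):
        mid = math.sqrt(lo * hi)  # geometric bisection on the scale
        f_mid = mean_identity(mid)
        closest = min(closest, (abs(f_mid - target_identity), mid, f_mid))
        if abs(f_mid - target_identity) <= tolerance:
            return replace(
                config, branch_length_mean=config.branch_length_mean * mid
            )
        if f_mid > target_identity:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not converge to {target_identity}% within "
        f"{max_iterations} iterations (closest {closest[2]:.1f}%)",
        closest=closest[2],
    )
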