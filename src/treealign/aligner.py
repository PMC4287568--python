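"""Progressive profile-profile alignment driven by an arbitrary guide-tree.

This is the deterministic "second stage" of progressive alignment: given
a guide-tree, sequences are merged bottom-up into profiles by global
affine-gap dynamic programming, scoring a pair of profile columns as the
sum-of-pairs substitution score over all residue pairs (gap characters
contribute nothing; gap penalties are charged per sequence pair).

The engine is intentionally plain: no sequence weighting, no iterative
refinement, no consistency transformation.  Iteration would modify the
alignment order and defeat the purpose of studying the guide-tree itself.

Two properties the guide-tree combinatorics rely on are enforced by
construction:

* **symmetry** — aligning (A, B) and (B, A) gives the same alignment:
  operands are put in a canonical order (by smallest sequence id) before
  the DP, whose tie-breaking is fixed (match > gap-in-second > gap-in-first);
* **determinism** — all scores are exact integers internally (the
  sum-of-pairs objective is multiplied by ``2 * n1 * n2``), so traceback
  comparisons never depend on floating-point rounding.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .family import ProteinFamily, SequenceRecord
from .trees import GuideTree, TreeError

GAP = "-"

#: Alphabet the aligner scores over (X = unknown, scored by the matrix's X row).
ALIGN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"


class AlignmentError(ValueError):
    """Raised for invalid aligner inputs."""


@lru_cache(maxsize=None)
def _substitution_matrix(name: str) -> np.ndarray:
    """A 21x21 integer substitution matrix over :data:`ALIGN_ALPHABET`."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    out = np.zeros((len(ALIGN_ALPHABET), len(ALIGN_ALPHABET)), dtype=np.int64)
    for i, a in enumerate(ALIGN_ALPHABET):
        for j, b in enumerate(ALIGN_ALPHABET):
            out[i, j] = int(mat[a][b])
    if not np.array_equal(out, out.T):
        raise AlignmentError(f"substitution matrix {name!r} is not symmetric")
    return out


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters of the profile aligner.

    ``gap_open``/``gap_extend`` are per-sequence-pair penalties in the
    same (half-bit) units as the substitution matrix; terminal gaps are
    penalized like internal ones unless ``free_end_gaps`` is set.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    free_end_gaps: bool = False

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise AlignmentError("need gap_open >= gap_extend >= 0")

    @property
    def matrix_values(self) -> np.ndarray:
        return _substitution_matrix(self.matrix)

    def fingerprint(self) -> str:
        return (
            f"{self.matrix};go={self.gap_open:g};ge={self.gap_extend:g};"
            f"ends={'free' if self.free_end_gaps else 'penalized'}"
        )


DEFAULT_PARAMS = AlignParams()

_CHAR_INDEX = {c: i for i, c in enumerate(ALIGN_ALPHABET)}


class Profile:
    """An alignment treated as a single alignable object.

    Rows are (sequence id, gapped string) pairs of equal length; the
    per-column residue counts (gaps excluded) drive the column scores.
    """

    __slots__ = ("rows", "_counts")

    def __init__(self, rows: Sequence[tuple[str, str]]) -> None:
        rows = [(str(i), str(s)) for i, s in rows]
        if not rows:
            raise AlignmentError("a profile needs at least one row")
        length = len(rows[0][1])
        ids = [i for i, _ in rows]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids in profile")
        for i, s in rows:
            if len(s) != length:
                raise AlignmentError("profile rows must have equal length")
        self.rows: list[tuple[str, str]] = rows
        self._counts: Optional[np.ndarray] = None

    @classmethod
    def from_sequence(cls, record: SequenceRecord) -> "Profile":
        return cls([(record.id, record.residues)])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def counts(self) -> np.ndarray:
        """Residue counts per column, shape (length, 21); gaps excluded."""
        if self._counts is None:
            counts = np.zeros((self.length, len(ALIGN_ALPHABET)), dtype=np.int64)
            for _, s in self.rows:
                for col, c in enumerate(s):
                    if c != GAP:
                        counts[col, _CHAR_INDEX[c]] += 1
            self._counts = counts
        return self._counts

    def column_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """(residue frequencies (length, 21), gap frequency (length,))."""
        counts = self.counts
        n = self.n_rows
        return counts / n, 1.0 - counts.sum(axis=1) / n

    def degapped(self, seq_id: str) -> str:
        for i, s in self.rows:
            if i == seq_id:
                return s.replace(GAP, "")
        raise KeyError(seq_id)

    def reorder(self, ids: Sequence[str]) -> "Profile":
        by_id = dict(self.rows)
        return Profile([(i, by_id[i]) for i in ids])

    def __eq__(self, other) -> bool:
        return isinstance(other, Profile) and self.rows == other.rows

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Profile({self.n_rows} rows x {self.length} cols)"


# --------------------------------------------------------------------------
# pairwise profile DP
# --------------------------------------------------------------------------

_NEG = -(1 << 40)


def _dp_matrices(W: np.ndarray, go: int, ge: int, free_ends: bool):
    """Fill the three affine-gap DP matrices (integer arithmetic).

    State M: columns i of A and j of B aligned; X: column of A against a
    gap; Y: column of B against a gap.  Y-runs live within a row, so they
    are filled with an exact running-maximum recurrence.
    """
    L1, L2 = W.shape
    M = np.full((L1 + 1, L2 + 1), _NEG, dtype=np.int64)
    X = np.full((L1 + 1, L2 + 1), _NEG, dtype=np.int64)
    Y = np.full((L1 + 1, L2 + 1), _NEG, dtype=np.int64)
    M[0, 0] = 0
    j_idx = np.arange(L2 + 1, dtype=np.int64)

    def fill_y(i: int) -> None:
        # Y[i, j] = max_{k <= j-1} M[i, k] - go - (j-1-k)*ge, exactly.
        base = M[i] + j_idx * ge
        runmax = np.maximum.accumulate(base[:-1])
        Y[i, 1:] = runmax - go - (j_idx[1:] - 1) * ge
        if free_ends and i == 0:
            Y[0, 1:] = 0

    fill_y(0)
    for i in range(1, L1 + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + W[i - 1]
        X[i] = np.maximum(M[i - 1] - go, X[i - 1] - ge)
        if free_ends:
            X[i, 0] = 0
        fill_y(i)
    return M, X, Y


def _traceback(M, X, Y, W, go, ge, start_state: str, i: int, j: int) -> list[str]:
    """Walk back from (i, j) emitting moves D (match), U (A col), L (B col).

    All comparisons are exact integer equalities against the recurrences
    that filled the matrices; ties prefer closing a gap (state M) and,
    from a match, the predecessor order M > X > Y.
    """
    moves: list[str] = []
    state = start_state
    while i > 0 or j > 0:
        if state == "M":
            moves.append("D")
            target = M[i, j] - W[i - 1, j - 1]
            i, j = i - 1, j - 1
            if M[i, j] == target:
                state = "M"
            elif X[i, j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            moves.append("U")
            state = "M" if M[i - 1, j] - go == X[i, j] else "X"
            i -= 1
        else:  # Y
            moves.append("L")
            state = "M" if M[i, j - 1] - go == Y[i, j] else "Y"
            j -= 1
    moves.reverse()
    return moves


def _pairwise_dp(p1: Profile, p2: Profile, params: AlignParams):
    """Core DP: returns (moves, integer score scaled by 2*n1*n2)."""
    B = params.matrix_values
    C1, C2 = p1.counts, p2.counts
    n1, n2 = p1.n_rows, p2.n_rows
    W = 2 * (C1 @ B @ C2.T)
    scale = n1 * n2
    go = int(round(2 * params.gap_open * scale))
    ge = int(round(2 * params.gap_extend * scale))
    M, X, Y = _dp_matrices(W, go, ge, params.free_end_gaps)
    L1, L2 = p1.length, p2.length

    if not params.free_end_gaps:
        score = max(M[L1, L2], X[L1, L2], Y[L1, L2])
        for state, mat in (("M", M), ("X", X), ("Y", Y)):  # tie: M > X > Y
            if mat[L1, L2] == score:
                break
        moves = _traceback(M, X, Y, W, go, ge, state, L1, L2)
    else:
        # Free trailing gaps: the alignment may end anywhere on the last
        # row or column; the remainder is padded with unpenalized gaps.
        # Ties prefer the longer alignment, then corner-ward, then M>X>Y.
        best = None
        ends = [(i, L2) for i in range(L1 + 1)] + [(L1, j) for j in range(L2)]
        for ei, ej in ends:
            for rank, (state, mat) in enumerate((("M", M), ("X", X), ("Y", Y))):
                cand = (int(mat[ei, ej]), ei + ej, -rank, ei, ej)
                if best is None or cand > best[0]:
                    best = (cand, state, ei, ej)
        (score, *_), state, ei, ej = best
        moves = _traceback(M, X, Y, W, go, ge, state, ei, ej)
        moves += ["U"] * (L1 - ei) + ["L"] * (L2 - ej)
    return moves, int(score), scale


def pairwise_score(a: SequenceRecord, b: SequenceRecord,
                   params: AlignParams = DEFAULT_PARAMS) -> float:
    """Optimal global affine-gap alignment score of two sequences."""
    _, score, scale = _pairwise_dp(
        Profile.from_sequence(a), Profile.from_sequence(b), params
    )
    return score / (2 * scale)


def align_profiles(p1: Profile, p2: Profile,
                   params: AlignParams = DEFAULT_PARAMS) -> Profile:
    """Globally align two profiles; the result holds all rows of both.

    Symmetric: the operand whose lexicographically smallest sequence id is
    smaller is always placed first internally, so ``align_profiles(a, b)``
    and ``align_profiles(b, a)`` build identical alignments (up to row
    order, which follows operand order).
    """
    if set(p1.ids) & set(p2.ids):
        raise AlignmentError("profiles share sequence ids")
    swapped = min(p2.ids) < min(p1.ids)
    a, b = (p2, p1) if swapped else (p1, p2)
    moves, _, _ = _pairwise_dp(a, b, params)
    rows_a = _apply_moves(a, moves, consume="UD")
    rows_b = _apply_moves(b, moves, consume="LD")
    merged = rows_a + rows_b
    if swapped:
        by_id = dict(merged)
        merged = [(i, by_id[i]) for i in p1.ids + p2.ids]
    return Profile(merged)


def _apply_moves(profile: Profile, moves: list[str], consume: str) -> list:
    out = []
    for seq_id, row in profile.rows:
        pos = 0
        chars = []
        for mv in moves:
            if mv in consume:
                chars.append(row[pos])
                pos += 1
            else:
                chars.append(GAP)
        assert pos == len(row)
        out.append((seq_id, "".join(chars)))
    return out


# --------------------------------------------------------------------------
# progressive alignment
# --------------------------------------------------------------------------

def progressive_align(
    family: Union[ProteinFamily, Iterable[SequenceRecord]],
    tree: GuideTree,
    params: AlignParams = DEFAULT_PARAMS,
    cache: Optional[dict] = None,
) -> Profile:
    """Align a family by post-order traversal of ``tree``.

    Branch lengths are ignored; only the merge order matters.  Output rows
    follow the input family order.  ``cache`` (canonical subtree newick ->
    Profile) lets exhaustive explorations reuse shared subtrees.
    """
    records = list(family.sequences) if isinstance(family, ProteinFamily) else list(family)
    by_id = {r.id: r for r in records}
    if set(tree.leaf_labels()) != set(by_id):
        raise AlignmentError(
            "guide-tree leaf labels do not match the family's sequence ids"
        )

    def build(node) -> Profile:
        if node.is_leaf:
            return Profile.from_sequence(by_id[node.label])
        if cache is not None:
            key = GuideTree(node, validate=False).canonical_newick()
            hit = cache.get(key)
            if hit is not None:
                return hit
        left = build(node.children[0])
        right = build(node.children[1])
        prof = align_profiles(left, right, params)
        if cache is not None:
            cache[key] = prof
        return prof

    result = build(tree.root)
    return result.reorder([r.id for r in records])
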