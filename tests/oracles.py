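"""Independent reference implementations used as test oracles.

Everything here is deliberately written in the most naive way possible
(recursive enumeration, per-cell loops) and shares no code with the
package, so agreement is meaningful.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np


# --------------------------------------------------------------------------
# labeled-tree enumeration by recursive set splitting
# --------------------------------------------------------------------------

def bruteforce_labeled_trees(labels) -> set:
    """All labeled rooted binary trees as nested frozensets.

    A leaf is its label; an internal node is the frozenset of its two
    child subtrees.  Splitting off the subset containing the smallest
    label generates each tree exactly once, but results are returned as
    a set so duplicates could not slip through anyway.
    """

    def trees(s: frozenset):
        items = sorted(s)
        if len(items) == 1:
            return [items[0]]
        first, rest = items[0], items[1:]
        out = []
        for r in range(len(rest)):
            for combo in combinations(rest, r):
                left = frozenset((first,) + combo)
                right = s - left
                if not right:
                    continue
                for lt in trees(left):
                    for rt in trees(frozenset(right) if not isinstance(right, frozenset) else right):
                        out.append(frozenset([lt, rt]))
        return out

    return set(trees(frozenset(labels)))


def tree_to_frozensets(node):
    """Convert a package tree node to the nested-frozenset representation."""
    if node.is_leaf:
        return node.label
    return frozenset(tree_to_frozensets(c) for c in node.children)


# --------------------------------------------------------------------------
# affine-gap alignment by exhaustive enumeration
# --------------------------------------------------------------------------

def _blosum():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def bruteforce_best_score(a: str, b: str, gap_open=10.0, gap_extend=0.5) -> float:
    """Maximum global alignment score by enumerating every alignment.

    Same column model as the package aligner: gap runs in the two
    sequences never directly abut (a column pair (gap, gap) is not
    representable), terminal gaps are penalized.
    """
    B = _blosum()
    best = -np.inf

    def rec(i, j, prev, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + B[a[i]][b[j]])
        if i < len(a) and prev != "Y":
            rec(i + 1, j, "X", score - (gap_extend if prev == "X" else gap_open))
        if j < len(b) and prev != "X":
            rec(i, j + 1, "Y", score - (gap_extend if prev == "Y" else gap_open))

    rec(0, 0, None, 0.0)
    return float(best)


# --------------------------------------------------------------------------
# naive progressive profile aligner (integer scores, per-cell loops)
# --------------------------------------------------------------------------

def _naive_profile_counts(rows):
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    idx = {c: i for i, c in enumerate(alphabet)}
    length = len(rows[0][1])
    counts = np.zeros((length, len(alphabet)), dtype=np.int64)
    for _, s in rows:
        for col, ch in enumerate(s):
            if ch != "-":
                counts[col, idx[ch]] += 1
    return counts


def naive_align_rows(rows_a, rows_b, gap_open=10.0, gap_extend=0.5):
    """Align two lists of (id, gapped string) rows; returns merged rows.

    Independent per-cell reimplementation of the same column model:
    integer sum-of-pairs scores scaled by 2*n1*n2, transitions
    M->{M,X,Y}, X->{M,X}, Y->{M,Y}, traceback ties preferring
    M over X over Y, operands in canonical order by smallest id.
    """
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    B = np.array([[int(mat[x][y]) for y in alphabet] for x in alphabet], dtype=np.int64)

    if min(i for i, _ in rows_b) < min(i for i, _ in rows_a):
        rows_a, rows_b = rows_b, rows_a
        swapped = True
    else:
        swapped = False

    C1, C2 = _naive_profile_counts(rows_a), _naive_profile_counts(rows_b)
    n1, n2 = len(rows_a), len(rows_b)
    W = 2 * (C1 @ B @ C2.T)
    go = int(round(2 * gap_open * n1 * n2))
    ge = int(round(2 * gap_extend * n1 * n2))
    L1, L2 = C1.shape[0], C2.shape[0]
    NEG = -(1 << 40)
    M = [[NEG] * (L2 + 1) for _ in range(L1 + 1)]
    X = [[NEG] * (L2 + 1) for _ in range(L1 + 1)]
    Y = [[NEG] * (L2 + 1) for _ in range(L1 + 1)]
    M[0][0] = 0
    for i in range(1, L1 + 1):
        X[i][0] = -(go + (i - 1) * ge)
    for j in range(1, L2 + 1):
        Y[0][j] = -(go + (j - 1) * ge)
    for i in range(1, L1 + 1):
        for j in range(1, L2 + 1):
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + W[i - 1][j - 1]
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge)
    # traceback
    i, j = L1, L2
    score = max(M[i][j], X[i][j], Y[i][j])
    state = "M" if M[i][j] == score else ("X" if X[i][j] == score else "Y")
    moves = []
    while i > 0 or j > 0:
        if state == "M":
            moves.append("D")
            target = M[i][j] - W[i - 1][j - 1]
            i, j = i - 1, j - 1
            if M[i][j] == target:
                state = "M"
            elif X[i][j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            moves.append("U")
            state = "M" if M[i - 1][j] - go == X[i][j] else "X"
            i -= 1
        else:
            moves.append("L")
            state = "M" if M[i][j - 1] - go == Y[i][j] else "Y"
            j -= 1
    moves.reverse()

    def expand(rows, take):
        out = []
        for seq_id, row in rows:
            pos = 0
            chars = []
            for mv in moves:
                if mv in take:
                    chars.append(row[pos])
                    pos += 1
                else:
                    chars.append("-")
            out.append((seq_id, "".join(chars)))
        return out

    merged = expand(rows_a, "UD") + expand(rows_b, "LD")
    if swapped:
        merged = merged[n1:] + merged[:n1]
    return merged


def naive_progressive(records, nested, gap_open=10.0, gap_extend=0.5):
    """Progressive alignment following a nested-tuple guide-tree."""
    by_id = {r.id: r for r in records}

    def build(obj):
        if isinstance(obj, str):
            return [(obj, by_id[obj].residues)]
        left, right = obj
        return naive_align_rows(build(left), build(right), gap_open, gap_extend)

    return dict(build(nested))


# --------------------------------------------------------------------------
# pair-counting SP oracle
# --------------------------------------------------------------------------

def bruteforce_sp(test_rows: dict, ref_rows: dict, core_cols) -> float:
    """SP score by explicit loops over sequence pairs and core columns."""

    def col_of_ordinal(row):
        return [c for c, ch in enumerate(row) if ch != "-"]

    def ordinal_at_col(row):
        out, k = {}, 0
        for c, ch in enumerate(row):
            if ch != "-":
                out[c] = k
                k += 1
        return out

    ids = sorted(ref_rows)
    test_cols = {i: col_of_ordinal(test_rows[i]) for i in ids}
    ref_ords = {i: ordinal_at_col(ref_rows[i]) for i in ids}
    good = total = 0
    for c in core_cols:
        for a, b in combinations(ids, 2):
            total += 1
            ta = test_cols[a][ref_ords[a][c]]
            tb = test_cols[b][ref_ords[b][c]]
            if ta == tb:
                good += 1
    return good / total
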