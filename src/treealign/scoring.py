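"""Reference-based alignment scoring: Total Column and Sum-of-Pairs.

Both scores are computed over *core columns* of a structure-derived
reference alignment — columns where every reference sequence has a
residue and (when superposed C-alpha coordinates are available) all
pairwise C-alpha distances fall within a threshold (0.3 nm by default).

Residues are identified by their per-sequence ordinal (the k-th non-gap
character), never by character equality, so repeated residues cannot
alias.  The test alignment may contain extra sequences; only the
reference sequences are scored.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .aligner import GAP, Profile


class ScoringError(ValueError):
    """Raised for malformed scoring inputs."""


class NoCoreColumnsError(ScoringError):
    """The reference has zero core columns: TC/SP are undefined.

    Signalled distinctly (rather than returned as 0) because averaging
    silent zeros over families would corrupt summaries.
    """


@dataclass
class ReferenceAlignment:
    """A reference MSA with a per-column core mask.

    ``ca_coords`` optionally maps sequence id to an (n_residues, 3) array
    of superposed C-alpha coordinates in nm, one row per non-gap residue.
    """

    alignment: Profile
    core_mask: np.ndarray
    ca_coords: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.core_mask = np.asarray(self.core_mask, dtype=bool)
        if self.core_mask.shape != (self.alignment.length,):
            raise ScoringError(
                f"core mask length {self.core_mask.size} != alignment "
                f"length {self.alignment.length}"
            )
        for _, row in self.alignment.rows:
            gapped = np.frombuffer(row.encode(), dtype=np.uint8) == ord(GAP)
            if (self.core_mask & gapped).any():
                raise ScoringError("core columns must be gap-free in every sequence")
        if self.ca_coords is not None:
            for seq_id, row in self.alignment.rows:
                n_res = len(row) - row.count(GAP)
                coords = np.asarray(self.ca_coords[seq_id], dtype=float)
                if coords.shape != (n_res, 3):
                    raise ScoringError(
                        f"{seq_id!r}: {coords.shape[0]} coordinates for "
                        f"{n_res} residues"
                    )

    @classmethod
    def from_profile(cls, alignment: Profile,
                     core_mask: Optional[np.ndarray] = None,
                     ca_coords: Optional[dict[str, np.ndarray]] = None,
                     ) -> "ReferenceAlignment":
        """Build a reference; the default mask marks all gap-free columns."""
        if core_mask is None:
            core_mask = np.array(
                [all(row[c] != GAP for _, row in alignment.rows)
                 for c in range(alignment.length)]
            )
        return cls(alignment=alignment, core_mask=core_mask, ca_coords=ca_coords)

    @property
    def n_core_columns(self) -> int:
        return int(self.core_mask.sum())


def core_columns(ref: ReferenceAlignment, threshold: float = 0.3) -> np.ndarray:
    """Recompute the core mask from superposed coordinates.

    A column is core iff no sequence has a gap there and every pairwise
    C-alpha distance within the column is <= ``threshold`` (nm).  The
    secondary-structure state is not restricted.
    """
    if ref.ca_coords is None:
        raise ScoringError("core_columns requires C-alpha coordinates")
    aln = ref.alignment
    # residue ordinal per (sequence, column); -1 at gaps
    ordinals = {}
    for seq_id, row in aln.rows:
        ords = np.full(len(row), -1, dtype=int)
        k = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                ords[c] = k
                k += 1
        ordinals[seq_id] = ords
    mask = np.zeros(aln.length, dtype=bool)
    ids = aln.ids
    for c in range(aln.length):
        if any(ordinals[i][c] < 0 for i in ids):
            continue
        pts = np.stack([ref.ca_coords[i][ordinals[i][c]] for i in ids])
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        mask[c] = bool((d <= threshold + 1e-12).all())
    return mask


def _column_map(profile: Profile, seq_id: str) -> np.ndarray:
    """Map residue ordinal -> column index for one row."""
    row = dict(profile.rows)[seq_id]
    return np.array([c for c, ch in enumerate(row) if ch != GAP], dtype=np.int64)


def _check_test(test: Profile, ref: ReferenceAlignment) -> list[str]:
    ids = ref.alignment.ids
    test_ids = set(test.ids)
    missing = [i for i in ids if i not in test_ids]
    if missing:
        raise ScoringError(f"test alignment is missing reference sequences {missing}")
    for i in ids:
        if test.degapped(i) != ref.alignment.degapped(i):
            raise ScoringError(
                f"sequence {i!r} differs between test and reference alignment"
            )
    if ref.n_core_columns == 0:
        raise NoCoreColumnsError("reference has no core columns")
    return ids


def _core_test_columns(test: Profile, ref: ReferenceAlignment):
    """For each core reference column, the test column of each sequence's
    residue; shape (n_core, n_sequences)."""
    ids = _check_test(test, ref)
    ref_maps = {i: _column_map(ref.alignment, i) for i in ids}
    test_maps = {i: _column_map(test, i) for i in ids}
    core = np.flatnonzero(ref.core_mask)
    out = np.empty((core.size, len(ids)), dtype=np.int64)
    for s, i in enumerate(ids):
        # ordinal of the residue sitting in each core reference column
        ref_cols = ref_maps[i]
        ord_of_col = np.full(ref.alignment.length, -1, dtype=np.int64)
        ord_of_col[ref_cols] = np.arange(ref_cols.size)
        out[:, s] = test_maps[i][ord_of_col[core]]
    return out


def tc_score(test: Profile, ref: ReferenceAlignment) -> float:
    """Fraction of core reference columns reproduced as whole columns.

    A core column counts as correct iff one test column holds exactly the
    same residues (by per-sequence ordinal) for all reference sequences.
    """
    cols = _core_test_columns(test, ref)
    correct = (cols == cols[:, :1]).all(axis=1)
    return float(correct.sum() / cols.shape[0])


def sp_score(test: Profile, ref: ReferenceAlignment) -> float:
    """Fraction of core-column residue pairs co-aligned in the test.

    Over all sequence pairs in all core reference columns, the fraction
    whose two residues share a test column.  Always >= the TC score.
    """
    cols = _core_test_columns(test, ref)
    n_seq = cols.shape[1]
    good = 0
    for a, b in combinations(range(n_seq), 2):
        good += int((cols[:, a] == cols[:, b]).sum())
    total = cols.shape[0] * (n_seq * (n_seq - 1) // 2)
    return float(good / total)
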