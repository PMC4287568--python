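"""Sequence records and protein families.

A :class:`ProteinFamily` bundles what a guide-tree benchmark needs for one
test case: the unaligned sequences, a trusted reference alignment with a
core-column mask, and (when known) the true tree the sequences evolved
under.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import ReferenceAlignment
    from .trees import GuideTree

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Alphabet accepted in sequence records ('X' = unknown residue).
SEQUENCE_ALPHABET = AMINO_ACIDS + "X"


class FamilyError(ValueError):
    """Raised for malformed sequence records or families."""


@dataclass(frozen=True)
class SequenceRecord:
    """An unaligned protein sequence with a unique identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FamilyError("sequence id must be non-empty")
        residues = self.residues.upper()
        if not residues:
            raise FamilyError(f"sequence {self.id!r} is empty")
        bad = set(residues) - set(SEQUENCE_ALPHABET)
        if bad:
            raise FamilyError(
                f"sequence {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )
        object.__setattr__(self, "residues", residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class ProteinFamily:
    """A named set of homologous sequences, optionally with ground truth.

    Parameters
    ----------
    name:
        Family identifier (e.g. a benchmark family name).
    sequences:
        The unaligned member sequences; ids must be unique.
    reference:
        Reference alignment with core-column mask, used for TC/SP scoring.
    true_tree:
        The tree the family is believed to have evolved under (simulated
        families carry the generating tree; real families an estimate).
    """

    name: str
    sequences: list[SequenceRecord]
    reference: Optional["ReferenceAlignment"] = None
    true_tree: Optional["GuideTree"] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise FamilyError(f"family {self.name!r} has duplicate sequence ids")
        if not ids:
            raise FamilyError(f"family {self.name!r} has no sequences")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def get(self, seq_id: str) -> SequenceRecord:
        for rec in self.sequences:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)
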