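"""Per-sequence and pairwise descriptors used for guide-tree construction.

These feed two consumers: distance matrices (k-tuple distance, pairwise
percent identity) and the sort keys used to populate chained guide-trees
(length, hydrophobic moment, isoelectric point, highest/lowest identity
to any other family member).
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Union

from .aligner import GAP, AlignParams, DEFAULT_PARAMS, Profile, align_profiles
from .family import ProteinFamily, SequenceRecord


class DescriptorError(ValueError):
    """Raised for invalid descriptor inputs."""


#: Eisenberg consensus hydrophobicity scale (dimensionless).
EISENBERG_SCALE = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
    "X": 0.0,  # unknown residue: no hydrophobicity contribution
}

#: EMBOSS pKa values for the ionizable groups.
PKA_POSITIVE = {"Nterm": 8.6, "H": 6.5, "K": 10.8, "R": 12.5}
PKA_NEGATIVE = {"Cterm": 3.6, "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1}


@dataclass(frozen=True)
class DescriptorSet:
    """All sort keys of one sequence within its family.

    ``hm``/``ip`` are the hydrophobic moment (Eisenberg units) and
    isoelectric point (pH); ``hml``/``ipl`` are the same normalised by
    sequence length; ``hi``/``lo`` are the highest/lowest percent
    identity to any other family member.
    """

    length: int
    hm: float
    hml: float
    ip: float
    ipl: float
    hi: float
    lo: float

    # lower-case aliases for key lookup
    @property
    def len(self) -> int:  # noqa: A003 - domain sort-key name
        return self.length


def ktuple_distance(a: SequenceRecord, b: SequenceRecord, k: int = 1) -> float:
    """Alignment-free distance from shared k-mer counts, in [0, 1].

    ``1 - shared/(min(len) - k + 1)`` where shared counts common k-tuples
    with multiplicity (min of the two counts).  k defaults to 1, the
    common choice for protein guide-tree distances.
    """
    if k < 1:
        raise DescriptorError(f"k must be >= 1, got {k}")
    if a.length < k or b.length < k:
        raise DescriptorError("sequence shorter than the tuple size")
    ca = Counter(a.residues[i:i + k] for i in range(a.length - k + 1))
    cb = Counter(b.residues[i:i + k] for i in range(b.length - k + 1))
    shared = sum(min(ca[t], cb[t]) for t in ca.keys() & cb.keys())
    denom = min(a.length, b.length) - k + 1
    return 1.0 - shared / denom


def percent_identity(a: SequenceRecord, b: SequenceRecord,
                     params: AlignParams = DEFAULT_PARAMS) -> float:
    """Percent identity after optimal global pairwise alignment.

    Uses the same engine and parameters as the progressive aligner.
    Identity = 100 * matches / columns where both sequences hold a
    residue (gap columns excluded from the denominator).
    """
    if a.id == b.id:
        a2 = SequenceRecord(id=a.id + "_a", residues=a.residues)
        b2 = SequenceRecord(id=b.id + "_b", residues=b.residues)
        return percent_identity(a2, b2, params)
    aln = align_profiles(Profile.from_sequence(a), Profile.from_sequence(b), params)
    row_a, row_b = (dict(aln.rows)[a.id], dict(aln.rows)[b.id])
    both = matches = 0
    for x, y in zip(row_a, row_b):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                matches += 1
    if both == 0:
        return 0.0
    return 100.0 * matches / both


def hydrophobic_moment(seq: Union[SequenceRecord, str],
                       delta: float = 100.0) -> float:
    """Mean hydrophobic moment magnitude at periodicity ``delta`` degrees.

    ``sqrt((sum_i H_i sin(i*delta))^2 + (sum_i H_i cos(i*delta))^2)`` with
    i = 1..L over the Eisenberg consensus scale; 100 degrees corresponds
    to the alpha-helical repeat.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    rad = math.radians(delta)
    s = c = 0.0
    for i, res in enumerate(residues, start=1):
        try:
            h = EISENBERG_SCALE[res]
        except KeyError:
            raise DescriptorError(f"no hydrophobicity value for residue {res!r}")
        s += h * math.sin(i * rad)
        c += h * math.cos(i * rad)
    return math.hypot(s, c)


def net_charge(residues: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Sums the N-terminus, C-terminus and the ionizable side chains
    (D, E, C, Y, H, K, R) with the EMBOSS pKa table; strictly decreasing
    in pH.
    """
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    counts = Counter(residues)
    for res in ("H", "K", "R"):
        charge += counts[res] / (1.0 + 10 ** (ph - PKA_POSITIVE[res]))
    for res in ("C", "D", "E", "Y"):
        charge -= counts[res] / (1.0 + 10 ** (PKA_NEGATIVE[res] - ph))
    return charge


def isoelectric_point(seq: Union[SequenceRecord, str],
                      tolerance: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    lo, hi = 0.0, 14.0
    if net_charge(residues, lo) < 0:
        return lo
    if net_charge(residues, hi) > 0:
        return hi
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if net_charge(residues, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def family_descriptors(
    family: Union[ProteinFamily, list[SequenceRecord]],
    params: AlignParams = DEFAULT_PARAMS,
    identity: Optional[dict[tuple[str, str], float]] = None,
) -> dict[str, DescriptorSet]:
    """All sort keys for every family member.

    ``hi``/``lo`` are the max/min percent identity to any *other* member;
    a precomputed pairwise ``identity`` map may be supplied to avoid
    realigning.
    """
    records = family.sequences if isinstance(family, ProteinFamily) else list(family)
    if len(records) < 2:
        raise DescriptorError("family descriptors need at least 2 sequences")
    if identity is None:
        identity = {}
        for i, a in enumerate(records):
            for b in records[i + 1:]:
                pid = percent_identity(a, b, params)
                identity[(a.id, b.id)] = pid
                identity[(b.id, a.id)] = pid
    out = {}
    for rec in records:
        pids = [identity[(rec.id, other.id)] for other in records if other.id != rec.id]
        hm = hydrophobic_moment(rec)
        ip = isoelectric_point(rec)
        out[rec.id] = DescriptorSet(
            length=rec.length,
            hm=hm,
            hml=hm / rec.length,
            ip=ip,
            ipl=ip / rec.length,
            hi=max(pids),
            lo=min(pids),
        )
    return out
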