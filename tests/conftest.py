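"""Shared fixtures: toy families, random alignments, simulated benchmarks."""
from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from treealign import (
    ProteinFamily,
    ReferenceAlignment,
    SequenceRecord,
    SimulationConfig,
    simulate_family,
)
from treealign.aligner import Profile


@pytest.fixture
def toy_tc_family():
    """3 identical 4-residue sequences: reference plus a half-right test.

    The test alignment reproduces exactly 2 of the 4 core columns, so
    TC = 0.5 and SP = 8/12 by hand enumeration.
    """
    ref = Profile([("x", "ACDE"), ("y", "ACDE"), ("z", "ACDE")])
    reference = ReferenceAlignment.from_profile(ref)
    test = Profile([("x", "ACDE-"), ("y", "AC-DE"), ("z", "ACDE-")])
    return test, reference


def random_alignment(records, rng, force_first_column=True) -> Profile:
    """A random valid alignment of the given sequences.

    Each row places its residues, in order, on a random subset of
    columns.  With ``force_first_column`` every row's first residue sits
    in column 0, guaranteeing at least one gap-free (core) column.
    """
    max_len = max(r.length for r in records)
    width = max_len + int(rng.integers(0, max_len // 2 + 2))
    rows = []
    for rec in records:
        start = 1 if force_first_column else 0
        positions = np.sort(
            rng.choice(np.arange(start, width), size=rec.length - start,
                       replace=False)
        )
        if force_first_column:
            positions = np.concatenate([[0], positions])
        chars = ["-"] * width
        for pos, res in zip(positions, rec.residues):
            chars[pos] = res
        rows.append((rec.id, "".join(chars)))
    return Profile(rows)


def random_records(rng, n=3, min_len=4, max_len=10) -> list[SequenceRecord]:
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append(SequenceRecord(
            id=f"s{i + 1}",
            residues="".join(rng.choice(aas, size=length)),
        ))
    return out


def study_families(n_families=10, n_sequences=5, seed=0) -> list[ProteinFamily]:
    """Simulated benchmark families spanning the easy-to-hard identity range.

    Branch-length scales are spread geometrically so mean pairwise
    identities cover roughly the 15-80% envelope of structure-derived
    benchmarks; root length 80 keeps exhaustive runs quick.
    """
    scales = np.geomspace(0.05, 0.8, n_families)
    families = []
    for i, scale in enumerate(scales):
        config = SimulationConfig(
            n_sequences=n_sequences,
            root_length=80,
            branch_length_mean=float(scale),
            indel_rate=0.05,
            seed=seed * 1000 + i,
        )
        families.append(simulate_family(config))
    return families


@pytest.fixture(scope="session")
def five_seq_families():
    return study_families(n_families=10, n_sequences=5, seed=1)
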