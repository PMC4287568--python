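"""File formats: FASTA, Newick, core-column masks, PHYLIP matrices, bundles.

All formats are plain text.  A *family bundle* is a directory holding one
simulated or curated family: unaligned FASTA, reference aligned FASTA,
core mask, true tree and a config echo.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .aligner import GAP, Profile
from .family import ProteinFamily, SequenceRecord
from .scoring import ReferenceAlignment
from .trees import GuideTree, Node, TreeError

PathLike = Union[str, Path]


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Unaligned sequences (gap characters are rejected)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if GAP in seq:
            raise ValueError(
                f"{rec.id!r} contains gaps; use read_alignment for aligned FASTA"
            )
        records.append(SequenceRecord(id=rec.id, residues=seq))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.residues[i:i + 60] + "\n")


def read_alignment(path: PathLike) -> Profile:
    """Aligned FASTA into a Profile."""
    from Bio import SeqIO

    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return Profile(rows)


def write_alignment(profile: Profile, path: PathLike) -> None:
    with open(path, "w") as fh:
        for seq_id, row in profile.rows:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i:i + 60] + "\n")


# --------------------------------------------------------------------------
# core-column masks and coordinates
# --------------------------------------------------------------------------

def read_mask(path: PathLike) -> np.ndarray:
    """A single line of 0/1 characters, one per alignment column."""
    text = Path(path).read_text().split()
    if len(text) != 1 or set(text[0]) - {"0", "1"}:
        raise ValueError(f"{path} is not a single-line 0/1 mask")
    return np.array([c == "1" for c in text[0]])


def write_mask(mask: np.ndarray, path: PathLike) -> None:
    Path(path).write_text("".join("1" if m else "0" for m in mask) + "\n")


def read_coords(path: PathLike) -> dict[str, np.ndarray]:
    """Superposed C-alpha coordinates: TSV of id, residue index, x, y, z (nm)."""
    table: dict[str, list] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        seq_id, idx, x, y, z = line.split("\t")
        table.setdefault(seq_id, []).append((int(idx), float(x), float(y), float(z)))
    out = {}
    for seq_id, rows in table.items():
        rows.sort()
        if [r[0] for r in rows] != list(range(len(rows))):
            raise ValueError(f"{seq_id!r}: residue indices must be 0..n-1")
        out[seq_id] = np.array([r[1:] for r in rows])
    return out


def write_coords(coords: dict[str, np.ndarray], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# id\tresidue\tx\ty\tz (nm)\n")
        for seq_id, arr in coords.items():
            for i, (x, y, z) in enumerate(np.asarray(arr)):
                fh.write(f"{seq_id}\t{i}\t{x:.6g}\t{y:.6g}\t{z:.6g}\n")


# --------------------------------------------------------------------------
# Newick
# --------------------------------------------------------------------------

def parse_newick(text: str, strict_binary: bool = True) -> Union[GuideTree, Node]:
    """Parse a Newick string.

    With ``strict_binary`` (the default) the result is a validated
    :class:`GuideTree`; a tree with any polytomy is rejected with a clear
    error.  With ``strict_binary=False`` the raw node structure is
    returned (used for unrooted trees destined for midpoint rooting).
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length
        children = [convert(c) for c in dnode.child_nodes()]
        return Node(label=label, children=children,
                    length=None if length is None else float(length))

    root = convert(dtree.seed_node)
    root.length = None
    if not strict_binary:
        return root
    for node in root.postorder():
        if node.children and len(node.children) != 2:
            raise TreeError(
                "tree is not strictly binary (a node has "
                f"{len(node.children)} children)"
            )
    return GuideTree(root)


def read_newick(path: PathLike, strict_binary: bool = True) -> Union[GuideTree, Node]:
    return parse_newick(Path(path).read_text(), strict_binary=strict_binary)


def write_newick(tree: GuideTree, path: PathLike,
                 with_lengths: Optional[bool] = None) -> None:
    Path(path).write_text(tree.newick(with_lengths=with_lengths) + "\n")


# --------------------------------------------------------------------------
# PHYLIP square distance matrix
# --------------------------------------------------------------------------

def write_phylip_matrix(matrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"{matrix.n}\n")
        for i, seq_id in enumerate(matrix.ids):
            vals = " ".join(f"{v:.6f}" for v in matrix.values[i])
            fh.write(f"{seq_id}  {vals}\n")


def read_phylip_matrix(path: PathLike):
    from .guide_builders import DistanceMatrix

    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    n = int(lines[0].split()[0])
    ids, rows = [], []
    for line in lines[1:n + 1]:
        parts = line.split()
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(ids=tuple(ids), values=np.array(rows))


# --------------------------------------------------------------------------
# family bundles
# --------------------------------------------------------------------------

BUNDLE_FILES = {
    "sequences": "sequences.fasta",
    "reference": "reference.afa",
    "mask": "core.mask",
    "tree": "true_tree.nwk",
    "config": "config.yaml",
}


def write_family_bundle(family: ProteinFamily, directory: PathLike) -> Path:
    """Write one family as a directory of plain-text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(family.sequences, directory / BUNDLE_FILES["sequences"])
    if family.reference is not None:
        write_alignment(family.reference.alignment,
                        directory / BUNDLE_FILES["reference"])
        write_mask(family.reference.core_mask, directory / BUNDLE_FILES["mask"])
    if family.true_tree is not None:
        write_newick(family.true_tree, directory / BUNDLE_FILES["tree"])
    config = getattr(family, "config", None)
    meta = {"name": family.name}
    if config is not None:
        cfg = {k: v for k, v in vars(config).items() if not k.startswith("_")}
        cfg["tree_source"] = (
            None if cfg.get("tree_source") is None
            else str(cfg["tree_source"])
        )
        meta["config"] = cfg
    (directory / BUNDLE_FILES["config"]).write_text(yaml.safe_dump(meta))
    return directory


def read_family_bundle(directory: PathLike) -> ProteinFamily:
    directory = Path(directory)
    sequences = read_fasta(directory / BUNDLE_FILES["sequences"])
    reference = None
    ref_path = directory / BUNDLE_FILES["reference"]
    if ref_path.exists():
        alignment = read_alignment(ref_path)
        mask_path = directory / BUNDLE_FILES["mask"]
        mask = read_mask(mask_path) if mask_path.exists() else None
        reference = ReferenceAlignment.from_profile(alignment, core_mask=mask)
    tree_path = directory / BUNDLE_FILES["tree"]
    true_tree = read_newick(tree_path) if tree_path.exists() else None
    name = directory.name
    config_path = directory / BUNDLE_FILES["config"]
    if config_path.exists():
        meta = yaml.safe_load(config_path.read_text()) or {}
        name = meta.get("name", name)
    return ProteinFamily(name=name, sequences=sequences,
                         reference=reference, true_tree=true_tree)
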