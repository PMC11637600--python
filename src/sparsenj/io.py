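"""File formats: aligned FASTA, PHYLIP distance matrices, Newick trees.

FASTA goes through Biopython; Newick parsing through dendropy (writing uses
the package's canonical serialiser so that write -> read -> write is
byte-identical).  The PHYLIP distance-matrix reader auto-detects the square
and lower-triangular dialects from the row shapes.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np

from .distances import SequenceMatrix, decode_sequence
from .simulate import WeightedTree
from .tree import Topology, from_newick, to_newick

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_phylip_matrix",
    "write_phylip_matrix",
    "read_tree",
    "write_tree",
]


def read_fasta(path: str | os.PathLike) -> SequenceMatrix:
    """Read an aligned DNA FASTA file into a :class:`SequenceMatrix`.

    Rejects duplicated taxon names and ragged alignments with explicit
    messages.
    """
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceMatrix.from_sequences(records)


def write_fasta(path: str | os.PathLike, seqs: SequenceMatrix,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for taxon in seqs.taxa:
            fh.write(f">{taxon}\n")
            s = decode_sequence(seqs.row(taxon))
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_phylip_matrix(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    """Read a PHYLIP distance matrix (square or lower-triangular).

    The dialect is detected from the row shapes: n values per row means
    square, 0..n-1 values means lower-triangular.  Returns the full
    symmetric matrix and the taxon names.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty distance-matrix file {path}")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise ValueError("first line must give the number of taxa") from None
    rows = []
    for ln in lines[1:]:
        fields = ln.split()
        try:
            vals = [float(x) for x in fields[1:]]
        except ValueError:
            raise ValueError(f"non-numeric distance entry in row {fields[0]!r}")
        rows.append((fields[0], vals))
    if len(rows) != n:
        raise ValueError(f"expected {n} matrix rows, found {len(rows)}")
    taxa = [name for name, _ in rows]
    if len(set(taxa)) != n:
        raise ValueError("duplicated taxon names in distance matrix")
    lens = [len(v) for _, v in rows]
    D = np.zeros((n, n), dtype=float)
    if lens == [n] * n:
        for i, (_, vals) in enumerate(rows):
            D[i] = vals
        asym = np.max(np.abs(D - D.T)) if n else 0.0
        if asym > 1e-9:
            raise ValueError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance 1e-09")
        D = (D + D.T) / 2.0
    elif lens == list(range(n)):
        for i, (_, vals) in enumerate(rows):
            D[i, :i] = vals
            D[:i, i] = vals
    else:
        raise ValueError("row shapes match neither the square nor the "
                         "lower-triangular PHYLIP dialect")
    np.fill_diagonal(D, 0.0)
    return D, taxa


def write_phylip_matrix(path: str | os.PathLike, matrix: np.ndarray,
                        taxa: Sequence[str]) -> None:
    D = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)}\n")
        for i, name in enumerate(taxa):
            vals = " ".join(f"{x:.10g}" for x in D[i])
            fh.write(f"{name} {vals}\n")


def read_tree(path: str | os.PathLike, *, with_lengths: bool = False):
    """Read a Newick tree file; optionally return a :class:`WeightedTree`."""
    with open(path) as fh:
        source = fh.read()
    if with_lengths:
        top, lengths = from_newick(source, with_lengths=True)
        return WeightedTree(top, lengths)
    return from_newick(source)


def write_tree(path: str | os.PathLike, tree: Topology | WeightedTree) -> None:
    if isinstance(tree, WeightedTree):
        text = tree.to_newick()
    else:
        text = to_newick(tree)
    with open(path, "w") as fh:
        fh.write(text + "\n")
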