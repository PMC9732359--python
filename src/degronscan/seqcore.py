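"""Sequence I/O, peptide tiling, hydropathy and composition utilities.

Everything downstream (PSI screening, degron prediction, TMD overlap,
simulation) works on the primitives defined here: protein records, 17-mer
peptide tiles, Kyte-Doolittle hydropathy and amino-acid composition vectors.

Coordinates are 1-based inclusive in every public interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("degronscan")

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Kyte & Doolittle (1982) hydropathy scale, per residue.
#: Values are the published table; do not edit.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: KD values ordered to match AMINO_ACIDS (used as a weight vector preset).
KD_VECTOR: np.ndarray = np.array([KYTE_DOOLITTLE[a] for a in AMINO_ACIDS])

#: Default library tile length (residues) and tiling step.
TILE_LENGTH = 17
TILE_STEP = 5


class SequenceError(ValueError):
    """Raised for invalid residues, short sequences, or malformed input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession.

    The sequence must be upper-case and restricted to the 20 canonical
    amino acids; use :func:`read_fasta` to apply a sanitization policy to
    raw database entries.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"{self.id}: empty sequence")
        validate_sequence(self.sequence, context=self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideTile:
    """One library tile: a window of a source protein.

    ``start`` is the 1-based inclusive index of the tile's first residue in
    the source protein; ``end`` is derived.
    """

    protein_id: str
    start: int
    sequence: str

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


def validate_sequence(sequence: str, context: str = "sequence") -> None:
    """Raise :class:`SequenceError` naming the first invalid residue."""
    for pos, aa in enumerate(sequence, start=1):
        if aa not in _AA_INDEX:
            raise SequenceError(
                f"{context}: invalid residue {aa!r} at position {pos}"
            )


def read_fasta(path, policy: str = "drop") -> list[ProteinRecord]:
    """Read a multi-FASTA file into :class:`ProteinRecord` objects.

    Parameters
    ----------
    path
        FASTA file path.
    policy
        How to treat entries containing residues outside the 20-letter
        alphabet (X, U, B, Z, ``*`` ...): ``"drop"`` excludes the whole
        protein with a logged warning (default; the degron model cannot
        score nonstandard residues), ``"keep"`` raises on the first
        invalid record.

    Raises
    ------
    SequenceError
        If the file contains no records or duplicate ids.
    """
    if policy not in ("drop", "keep"):
        raise ValueError(f"unknown sanitization policy {policy!r}")
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    dropped: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().rstrip("*")
        seen[entry.id] = seen.get(entry.id, 0) + 1
        if any(aa not in _AA_INDEX for aa in seq) or not seq:
            if policy == "drop":
                dropped.append(entry.id)
                continue
            validate_sequence(seq, context=entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    duplicates = sorted(k for k, v in seen.items() if v > 1)
    if duplicates:
        raise SequenceError(f"duplicate FASTA ids: {', '.join(duplicates)}")
    if not seen:
        raise SequenceError(f"{path}: no FASTA records found")
    if dropped:
        logger.warning(
            "read_fasta: dropped %d record(s) with nonstandard residues: %s",
            len(dropped), ", ".join(dropped[:10]),
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def tile_sequence(
    sequence: str,
    window: int = TILE_LENGTH,
    step: int = TILE_STEP,
    anchor_tail: bool = False,
    protein_id: str = "",
) -> list[PeptideTile]:
    """Cut a sequence into overlapping tiles.

    Tiles start at 1, 1+step, 1+2*step, ... while a full window fits. With
    ``anchor_tail``, if the last regular tile does not reach the C-terminus
    one extra tile anchored at ``L - window + 1`` is appended, so the tail
    of the protein is always covered (this mirrors library designs that add
    a final C-terminal oligo). Proteome scanning uses ``window=17, step=1``
    without the anchor.

    Raises
    ------
    SequenceError
        If the sequence is shorter than the window.
    """
    L = len(sequence)
    if L < window:
        raise SequenceError(
            f"{protein_id or 'sequence'} of length {L} is shorter than "
            f"window {window}"
        )
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    starts = list(range(1, L - window + 2, step))
    if anchor_tail and starts[-1] + window - 1 < L:
        starts.append(L - window + 1)
    return [
        PeptideTile(protein_id=protein_id, start=s,
                    sequence=sequence[s - 1: s - 1 + window])
        for s in starts
    ]


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    if not sequence:
        raise SequenceError("gravy: empty sequence")
    validate_sequence(sequence, context="gravy")
    return sum(KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)


def composition(sequence: str) -> np.ndarray:
    """Amino-acid composition of a sequence.

    Returns a length-20 vector of residue fractions ordered by
    :data:`AMINO_ACIDS`; entries sum to 1. Composition is an order-free
    statistic: any permutation of the sequence yields the same vector.
    """
    if not sequence:
        raise SequenceError("composition: empty sequence")
    validate_sequence(sequence, context="composition")
    counts = np.zeros(len(AMINO_ACIDS))
    for aa in sequence:
        counts[_AA_INDEX[aa]] += 1
    return counts / len(sequence)


def composition_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Stack :func:`composition` vectors for many sequences (n x 20)."""
    return np.array([composition(s) for s in sequences])


def scramble(sequence: str, seed: int) -> str:
    """A uniformly random permutation of the sequence; reproducible by seed."""
    validate_sequence(sequence, context="scramble")
    rng = np.random.default_rng(seed)
    letters = list(sequence)
    rng.shuffle(letters)
    return "".join(letters)


def tiles_to_tsv(tiles: Iterable[PeptideTile], path) -> None:
    """Export tiles as TSV: protein_id, start, end, sequence (1-based)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tsequence\n")
        for t in tiles:
            fh.write(f"{t.protein_id}\t{t.start}\t{t.end}\t{t.sequence}\n")
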