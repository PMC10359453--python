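"""Aligned-FASTA I/O and reference-coordinate mapping.

An :class:`Msa` is an ordered, immutable collection of equal-length protein
sequences over the 20-letter amino-acid alphabet plus gap ``-`` and unknown
``X``.  All downstream reporting uses the residue numbering of a designated
reference sequence (for this project, *Msm*UdgX); :class:`ReferenceMap`
translates between 1-based alignment columns and 1-based ungapped reference
positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import GAP, UNKNOWN, VALID_CHARS
from .exceptions import (
    AlignmentFormatError,
    AlignmentValidationError,
    ReferenceLookupError,
)

logger = logging.getLogger(__name__)

__all__ = ["Msa", "ReferenceMap", "read_alignment", "write_alignment", "build_reference_map"]


@dataclass(frozen=True)
class Msa:
    """An immutable multiple sequence alignment.

    Parameters
    ----------
    ids :
        Sequence identifiers, unique, in file order.
    sequences :
        Aligned sequences, all of identical length, uppercase, over the
        alphabet ``{20 amino acids, '-', 'X'}``.
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentValidationError("ids and sequences differ in number")
        if not self.ids:
            raise AlignmentValidationError("alignment contains no sequences")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentValidationError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if self.length < 1:
            raise AlignmentValidationError("alignment length must be >= 1")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.sequences[0])

    @property
    def records(self) -> Iterator[tuple[str, str]]:
        return zip(self.ids, self.sequences)

    # -- access ------------------------------------------------------------
    def get(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise ReferenceLookupError(f"sequence id {seq_id!r} not in alignment") from None

    def column(self, col: int) -> str:
        """Characters of 1-based alignment column *col*, in sequence order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        i = col - 1
        return "".join(s[i] for s in self.sequences)

    def subset(self, ids: Sequence[str]) -> "Msa":
        """Restriction to the given ids, preserving their order in *ids*."""
        return Msa(tuple(ids), tuple(self.get(i) for i in ids))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Msa)
            and self.ids == other.ids
            and self.sequences == other.sequences
        )

    def __hash__(self) -> int:
        return hash((self.ids, self.sequences))


def _normalise(seq: str, seq_id: str) -> str:
    """Uppercase and map characters outside the alphabet to ``X``."""
    up = seq.upper()
    if all(c in VALID_CHARS for c in up):
        return up
    bad = sorted({c for c in up if c not in VALID_CHARS})
    logger.warning("sequence %r: non-standard characters %s mapped to %r", seq_id, bad, UNKNOWN)
    return "".join(c if c in VALID_CHARS else UNKNOWN for c in up)


def read_alignment(path: str | Path) -> Msa:
    """Read an aligned protein FASTA file.

    Sequences are uppercased; characters outside the alphabet are replaced
    by ``X`` with a logged warning.

    Raises
    ------
    AlignmentFormatError
        Empty file or duplicate ids.
    AlignmentValidationError
        Sequences of unequal length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: no FASTA records found")
    ids = tuple(r.id for r in records)
    seqs = tuple(_normalise(str(r.seq), r.id) for r in records)
    return Msa(ids, seqs)


def write_alignment(msa: Msa, path: str | Path) -> None:
    """Write *msa* as aligned FASTA (round-trips through :func:`read_alignment`)."""
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in msa.records]
    SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class ReferenceMap:
    """Bijection between alignment columns and reference residue positions.

    Both coordinate systems are 1-based.  Columns where the reference
    sequence carries a gap have no reference position and are absent from
    the mapping; conversely every ungapped reference residue 1..n_ref maps
    to exactly one column.
    """

    ref_id: str
    col_to_refpos: Mapping[int, int] = field(repr=False)
    refpos_to_col: Mapping[int, int] = field(repr=False)

    @property
    def n_ref(self) -> int:
        """Length of the ungapped reference sequence."""
        return len(self.refpos_to_col)

    def refpos_for(self, col: int) -> int:
        try:
            return self.col_to_refpos[col]
        except KeyError:
            raise ReferenceLookupError(
                f"alignment column {col} has no reference position (reference gap?)"
            ) from None

    def col_for(self, refpos: int) -> int:
        try:
            return self.refpos_to_col[refpos]
        except KeyError:
            raise ReferenceLookupError(
                f"reference position {refpos} outside 1..{self.n_ref}"
            ) from None

    def __contains__(self, refpos: int) -> bool:
        return refpos in self.refpos_to_col


def build_reference_map(msa: Msa, ref_id: str) -> ReferenceMap:
    """Map alignment columns to the ungapped numbering of sequence *ref_id*.

    Column *c* maps to reference position *p* iff the reference sequence has
    its *p*-th non-gap character at column *c*.  ``X`` in the reference is a
    residue position (it occupies reference numbering) even though it is
    excluded from statistics.
    """
    ref = msa.get(ref_id)
    col_to_refpos: dict[int, int] = {}
    p = 0
    for c, ch in enumerate(ref, start=1):
        if ch != GAP:
            p += 1
            col_to_refpos[c] = p
    if p == 0:
        raise AlignmentValidationError(f"reference {ref_id!r} is all gaps")
    refpos_to_col = {v: k for k, v in col_to_refpos.items()}
    return ReferenceMap(ref_id=ref_id, col_to_refpos=col_to_refpos, refpos_to_col=refpos_to_col)
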