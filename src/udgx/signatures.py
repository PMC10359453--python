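"""Signature-residue partitioning and subfamily comparison.

The evolutionary core of the pipeline: split an alignment into subfamilies
by fixed residues at reference positions (for UdgX-type enzymes, R107/H109
against the canonical family-4 P107/N109), list positions conserved above a
threshold within a subfamily, find the positions whose conserved residue is
unique to one subfamily, and measure co-occurrence of a query residue among
signature-matched sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from ._alphabet import AA_SET
from .conservation import column_profile
from .exceptions import ConfigError, InsufficientDataError
from .msa import Msa, ReferenceMap

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureSpec",
    "Partition",
    "UDGX_SIGNATURE",
    "FAMILY4_SIGNATURE",
    "partition_by_signature",
    "classify_subfamilies",
    "conserved_positions",
    "unique_conserved",
    "co_occurrence_fraction",
]


@dataclass(frozen=True)
class SignatureSpec:
    """Ordered set of (reference position, allowed residues) constraints.

    A sequence matches the signature iff at every listed position its
    character belongs to the allowed set; gaps and ``X`` never match.
    """

    positions: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self) -> None:
        seen = set()
        for refpos, residues in self.positions:
            if refpos in seen:
                raise ConfigError(f"duplicate signature position {refpos}")
            seen.add(refpos)
            if not residues:
                raise ConfigError(f"empty residue set at position {refpos}")
            bad = set(residues) - AA_SET
            if bad:
                raise ConfigError(f"non-standard residues {sorted(bad)} at position {refpos}")

    @classmethod
    def from_dict(cls, spec: Mapping[int, Iterable[str] | str]) -> "SignatureSpec":
        """Build from ``{refpos: residues}``, e.g. ``{107: "R", 109: "H"}``."""
        return cls(tuple((int(p), frozenset(r)) for p, r in spec.items()))

    def refpositions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.positions)

    def to_dict(self) -> dict[int, str]:
        return {p: "".join(sorted(r)) for p, r in self.positions}


#: R-loop signature of UdgX-type sequences
UDGX_SIGNATURE = SignatureSpec.from_dict({107: "R", 109: "H"})
#: canonical family-4 UDG residues at the same positions
FAMILY4_SIGNATURE = SignatureSpec.from_dict({107: "P", 109: "N"})


@dataclass(frozen=True)
class Partition:
    """Result of a signature split: matched ids, the rest, and the signature."""

    matched_ids: tuple[str, ...]
    unmatched_ids: tuple[str, ...]
    signature: SignatureSpec

    @property
    def n_matched(self) -> int:
        return len(self.matched_ids)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched_ids)


def _matches(seq: str, cols_allowed: list[tuple[int, frozenset[str]]]) -> bool:
    return all(seq[c - 1] in allowed for c, allowed in cols_allowed)


def partition_by_signature(msa: Msa, refmap: ReferenceMap, sig: SignatureSpec) -> Partition:
    """Split *msa* into sequences matching *sig* and the rest (order kept)."""
    cols_allowed = [(refmap.col_for(p), allowed) for p, allowed in sig.positions]
    matched, unmatched = [], []
    for sid, seq in msa.records:
        (matched if _matches(seq, cols_allowed) else unmatched).append(sid)
    return Partition(tuple(matched), tuple(unmatched), sig)


def classify_subfamilies(
    msa: Msa,
    refmap: ReferenceMap,
    udgx_sig: SignatureSpec = UDGX_SIGNATURE,
    family4_sig: SignatureSpec = FAMILY4_SIGNATURE,
) -> dict[str, tuple[str, ...]]:
    """Three-way split: UdgX-signature matches, family-4 matches, unclassified.

    Sequences failing both signatures (e.g. R107 without H109) are reported
    under ``"unclassified"`` rather than silently lumped with either group.
    """
    udgx = partition_by_signature(msa, refmap, udgx_sig)
    rest = msa.subset(udgx.unmatched_ids) if udgx.unmatched_ids else None
    if rest is None:
        return {"udgx": udgx.matched_ids, "family4": (), "unclassified": ()}
    fam4 = partition_by_signature(rest, refmap, family4_sig)
    return {
        "udgx": udgx.matched_ids,
        "family4": fam4.matched_ids,
        "unclassified": fam4.unmatched_ids,
    }


def conserved_positions(
    msa: Msa, refmap: ReferenceMap, threshold: float
) -> list[tuple[int, str, float]]:
    """Reference positions whose consensus frequency strictly exceeds *threshold*.

    Frequencies are over countable residues at that column (gap-bearing
    sequences drop out of the denominator).  Returns ``(refpos, consensus
    residue, fraction)`` sorted by refpos.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    out = []
    for refpos in sorted(refmap.refpos_to_col):
        p = column_profile(msa, refmap.col_for(refpos), refmap)
        if p.consensus is None:
            continue
        res, frac = p.consensus
        if frac > threshold:
            out.append((refpos, res, frac))
    return out


def unique_conserved(
    group_a: Msa,
    group_b: Msa,
    refmap: ReferenceMap,
    threshold: float,
) -> list[tuple[int, str, Optional[str]]]:
    """Positions conserved in *group_a* whose consensus differs from *group_b*'s.

    Both groups must live in the same alignment coordinate system as
    *refmap*.  Positions where *group_b* has no countable residue are
    skipped with a warning.  Returns ``(refpos, residue_a,
    consensus_b)`` sorted by refpos.
    """
    out = []
    for refpos, res_a, _frac in conserved_positions(group_a, refmap, threshold):
        pb = column_profile(group_b, refmap.col_for(refpos), refmap)
        if pb.consensus is None:
            logger.warning("refpos %d: no countable residues in comparison group; skipped", refpos)
            continue
        res_b = pb.consensus[0]
        if res_b != res_a:
            out.append((refpos, res_a, res_b))
    return out


def co_occurrence_fraction(
    msa: Msa,
    refmap: ReferenceMap,
    anchor: SignatureSpec,
    query_pos: int,
    query_residues: Iterable[str] | str,
) -> float:
    """Fraction of anchor-matched sequences carrying a query residue.

    ``|match(anchor) and residue at query_pos in query_residues| /
    |match(anchor)|``.  Raises :class:`InsufficientDataError` when no
    sequence matches the anchor.
    """
    part = partition_by_signature(msa, refmap, anchor)
    if part.n_matched == 0:
        raise InsufficientDataError("no sequences match the anchor signature")
    allowed = frozenset(query_residues)
    qcol = refmap.col_for(query_pos)
    hits = sum(1 for sid in part.matched_ids if msa.get(sid)[qcol - 1] in allowed)
    return hits / part.n_matched
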