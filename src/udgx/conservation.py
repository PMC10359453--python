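"""Per-column conservation statistics of a protein alignment.

For each alignment column: residue counts, frequencies over countable
characters (gaps and ``X`` excluded), the consensus residue, Shannon
entropy in bits, and the percent-occurrence table used for motif plots
(where gaps *do* count toward the denominator, because the published
convention divides by the total number of aligned sequences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from ._alphabet import GAP, UNKNOWN
from .exceptions import InsufficientDataError
from .msa import Msa, ReferenceMap

__all__ = [
    "PositionProfile",
    "column_profile",
    "percent_occurrence",
    "shannon_entropy",
    "joint_entropy",
    "profile_table",
]


def shannon_entropy(frequencies: Mapping[str, float]) -> float:
    """Shannon entropy in bits of a frequency distribution.

    Zero-probability entries contribute nothing; an empty mapping has
    entropy 0 by convention.
    """
    h = -sum(p * math.log2(p) for p in frequencies.values() if p > 0.0)
    return max(h, 0.0)


@dataclass(frozen=True)
class PositionProfile:
    """Residue statistics of one alignment column.

    ``frequencies`` are over countable characters only (the 20 amino
    acids); ``consensus`` is ``(residue, fraction)`` with ties broken
    alphabetically, or ``None`` when the column holds no countable
    character (then ``degenerate`` is set and ``entropy_bits`` is 0).
    """

    column: int
    refpos: Optional[int]
    counts: Mapping[str, int]
    gap_count: int
    x_count: int
    frequencies: Mapping[str, float] = field(repr=False)
    consensus: Optional[tuple[str, float]]
    entropy_bits: float
    degenerate: bool = False

    @property
    def n_countable(self) -> int:
        return sum(self.counts.values())


def _column_counts(chars: str) -> tuple[dict[str, int], int, int]:
    counts: dict[str, int] = {}
    gap = x = 0
    for ch in chars:
        if ch == GAP:
            gap += 1
        elif ch == UNKNOWN:
            x += 1
        else:
            counts[ch] = counts.get(ch, 0) + 1
    return counts, gap, x


def column_profile(msa: Msa, column: int, refmap: Optional[ReferenceMap] = None) -> PositionProfile:
    """Profile of 1-based alignment column *column*.

    Raises ``IndexError`` when *column* is out of range.  A column holding
    only gaps/``X`` yields an empty frequency table with entropy 0 and the
    ``degenerate`` flag set.
    """
    chars = msa.column(column)  # range-checks
    counts, gap, x = _column_counts(chars)
    refpos = None
    if refmap is not None:
        refpos = refmap.col_to_refpos.get(column)
    n = sum(counts.values())
    if n == 0:
        return PositionProfile(
            column=column, refpos=refpos, counts={}, gap_count=gap, x_count=x,
            frequencies={}, consensus=None, entropy_bits=0.0, degenerate=True,
        )
    freqs = {a: c / n for a, c in sorted(counts.items())}
    # max frequency, ties broken by alphabetical order of the one-letter code
    cons_res = min(freqs, key=lambda a: (-freqs[a], a))
    return PositionProfile(
        column=column, refpos=refpos, counts=dict(sorted(counts.items())),
        gap_count=gap, x_count=x, frequencies=freqs,
        consensus=(cons_res, freqs[cons_res]), entropy_bits=shannon_entropy(freqs),
    )


def percent_occurrence(msa: Msa, refmap: ReferenceMap, refpos: int) -> dict[str, float]:
    """Percent occurrence of each character at reference position *refpos*.

    Percentages are ``100 * count / n_sequences``: every aligned sequence
    counts toward the denominator, and gaps/``X`` appear as their own
    categories, so the table sums to 100.  This is the convention of the
    published percent-occurrence plots ("occurrences divided by the total
    number of samples").
    """
    col = refmap.col_for(refpos)
    chars = msa.column(col)
    n = msa.n_sequences
    out: dict[str, float] = {}
    for ch in chars:
        out[ch] = out.get(ch, 0.0) + 1.0
    return {ch: 100.0 * c / n for ch, c in sorted(out.items())}


def joint_entropy(msa: Msa, col_i: int, col_j: int) -> float:
    """Joint Shannon entropy H(i, j) in bits of two alignment columns.

    Computed over sequences holding a countable residue at *both* columns
    (pairwise deletion).  Requires at least 2 jointly countable sequences.
    """
    ci, cj = msa.column(col_i), msa.column(col_j)
    pairs: dict[tuple[str, str], int] = {}
    for a, b in zip(ci, cj):
        if a in (GAP, UNKNOWN) or b in (GAP, UNKNOWN):
            continue
        pairs[(a, b)] = pairs.get((a, b), 0) + 1
    n = sum(pairs.values())
    if n < 2:
        raise InsufficientDataError(
            f"columns {col_i},{col_j}: only {n} jointly countable sequences"
        )
    return -sum((c / n) * math.log2(c / n) for c in pairs.values())


def profile_table(msa: Msa, refmap: Optional[ReferenceMap] = None) -> pd.DataFrame:
    """One row per alignment column: refpos, counts, consensus, entropy.

    The returned frame serialises naturally to the TSV conservation report.
    """
    rows = []
    for col in range(1, msa.length + 1):
        p = column_profile(msa, col, refmap)
        cons_res, cons_frac = p.consensus if p.consensus else ("", float("nan"))
        rows.append(
            {
                "column": p.column,
                "refpos": p.refpos,
                "n_countable": p.n_countable,
                "gap_count": p.gap_count,
                "x_count": p.x_count,
                "consensus": cons_res,
                "consensus_fraction": cons_frac,
                "entropy_bits": p.entropy_bits,
                "counts": ",".join(f"{a}:{c}" for a, c in p.counts.items()),
            }
        )
    return pd.DataFrame(rows)
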