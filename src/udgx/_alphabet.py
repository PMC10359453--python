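"""Shared residue alphabet.

The 20 standard amino acids, a gap character and an unknown character.
Ambiguity and non-standard codes (B, Z, J, U, O, '*', '.') are normalised
to the unknown character on input; 'X' never enters residue statistics.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
GAP = "-"
UNKNOWN = "X"

#: input characters silently rewritten to UNKNOWN (with a logged warning)
NON_STANDARD = frozenset("BZJUO*.")

VALID_CHARS = AA_SET | {GAP, UNKNOWN}


def is_residue(ch: str) -> bool:
    """True for one of the 20 standard amino-acid letters."""
    return ch in AA_SET
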