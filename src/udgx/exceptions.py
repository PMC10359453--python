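"""Exception hierarchy for the udgx package."""


class UdgxError(Exception):
    """Base class for all package-specific errors."""


class AlignmentFormatError(UdgxError):
    """Malformed FASTA input (empty file, duplicate ids, unparseable records)."""


class AlignmentValidationError(UdgxError):
    """Alignment invariant violated (ragged rows, empty alignment)."""


class ReferenceLookupError(UdgxError, KeyError):
    """Reference id or reference position cannot be resolved."""


class InsufficientDataError(UdgxError):
    """Too few observations for the requested statistic."""


class KineticsFitError(UdgxError):
    """Kinetics regression failed (non-positive intercept, non-convergence)."""


class AtomSelectionError(UdgxError):
    """Atom selector resolved to zero or more than one atom."""


class StructureFormatError(UdgxError):
    """Unparseable or invalid coordinate file."""


class ConfigError(UdgxError):
    """Inconsistent configuration or simulation truth record."""
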