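"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors exit 2 (handled by
click), I/O errors exit 3, validation/format errors exit 4.
"""


class FlexlogoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FlexlogoError):
    """Input file violates the declared dialect (ragged lines, bad FASTA...)."""


class DialectError(FormatError):
    """Record does not satisfy the dialect contract (e.g. no uppercase run)."""


class EmptyInputError(FormatError):
    """Input contained no sequences."""


class ValidationError(FlexlogoError, ValueError):
    """A value or matrix violates a documented invariant."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class AmbiguousDimerError(ValidationError):
    """Dinucleotide contains a non-ACGT character; caller decides masking."""
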