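"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: usage errors exit 2, validation
errors 3, I/O and format errors 4.
"""


class CernetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(CernetError):
    """Input violates a documented invariant (bad ids, shapes, thresholds)."""

    exit_code = 3


class FormatError(CernetError):
    """A file does not conform to its declared dialect (TSV/GMT/FASTA)."""

    exit_code = 4


class ParseError(FormatError):
    """A cell or field could not be parsed; message names the location."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation requested on a zero-variance vector."""
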