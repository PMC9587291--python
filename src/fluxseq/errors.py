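"""Exception hierarchy.

Validation errors (bad user input, malformed files, inconsistent shapes)
are distinguished from runtime failures so the CLI can map them to exit
code 1 vs 2.
"""


class FluxseqError(Exception):
    """Base class for all package errors."""


class ValidationError(FluxseqError, ValueError):
    """Invalid argument, configuration, or inconsistent data."""


class FormatError(ValidationError):
    """Malformed on-disk artifact; message carries file/row/column context."""


class NumericalError(FluxseqError, ArithmeticError):
    """Ill-conditioned or non-convergent numerical problem."""
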