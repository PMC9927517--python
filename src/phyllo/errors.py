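"""Exception hierarchy.

``ValidationError`` covers malformed or inconsistent inputs (exit code 2 in
the CLI); ``ComputationError`` covers failures arising during an otherwise
well-posed computation (exit code 3).
"""


class PhylloError(Exception):
    """Base class for all package errors."""


class ValidationError(PhylloError):
    """Input file or argument failed validation; message names the offender."""


class ComputationError(PhylloError):
    """A computation could not be completed (e.g. a fit found no optimum)."""
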