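"""Exception hierarchy for the pipeline.

Validation failures (bad arguments, inconsistent shapes, invalid configs)
and estimation failures (degenerate data) are kept distinct so the CLI can
map them to different exit codes.
"""


class VesiflowError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(VesiflowError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(VesiflowError, ValueError):
    """A file on disk is not in the expected format."""


class EstimationError(VesiflowError, RuntimeError):
    """A well-formed input yields no usable estimate (e.g. empty mask)."""
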