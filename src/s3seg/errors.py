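"""Package exception hierarchy.

``DataError`` covers malformed or out-of-domain inputs (CLI exit code 3);
``NumericalError`` covers solver and conditioning failures (exit code 4).
"""


class S3SegError(Exception):
    """Base class for all s3seg errors."""


class DataError(S3SegError):
    """Invalid, inconsistent, or out-of-domain input data."""


class NumericalError(S3SegError):
    """A numerical procedure failed (non-convergence, infeasibility, ...)."""
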