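"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 1, data errors -> 2,
numerical failures -> 3.
"""


class SnpMriError(Exception):
    """Base class for all package errors."""


class UsageError(SnpMriError):
    """Bad arguments or configuration."""


class DataError(SnpMriError):
    """Malformed, inconsistent, or empty input data."""


class NumericalError(SnpMriError):
    """Numerical failure (divergence, degenerate values)."""
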