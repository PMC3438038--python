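"""Exception hierarchy.

``ValidationError`` signals bad inputs or configuration caught before any
computation; ``TrackingError`` and ``QuantError`` signal stage failures.
The CLI maps these to exit codes 2 and 3 respectively.
"""


class TagsyncError(Exception):
    """Base class for all package errors."""


class ValidationError(TagsyncError, ValueError):
    """Invalid configuration or input data (fail-fast, exit code 2)."""


class TrackingError(TagsyncError, RuntimeError):
    """HARP tracking failure (signal void, divergence, track quality)."""


class QuantError(TagsyncError, RuntimeError):
    """Degenerate input to a quantification stage."""
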