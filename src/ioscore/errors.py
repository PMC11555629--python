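"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`ValidationError` -> 2,
:class:`DataError` -> 3, anything else -> 4.
"""


class IOScoreError(Exception):
    """Base class for all package errors."""


class ValidationError(IOScoreError):
    """A configuration value or parameter is outside its documented range."""


class DataError(IOScoreError):
    """An input file or table violates its contract (format, ids, signs)."""
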