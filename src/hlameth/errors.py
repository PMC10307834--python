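"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and its subclass
``ParseError``) to exit code 3.
"""


class HlamethError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HlamethError):
    """Invalid configuration: missing columns, bad thresholds, unknown region."""


class DataError(HlamethError):
    """Input data violates a contract (axis mismatch, empty group, ...)."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending row/cell."""
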