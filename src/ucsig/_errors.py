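"""Exception hierarchy shared across the package.

Reader errors always carry enough context (file, line, column) to locate
the offending input without re-parsing it by hand.
"""


class UcsigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(UcsigError):
    """A file does not conform to its expected format (missing column, bad field)."""


class ValidationError(UcsigError):
    """Parsed content violates a domain invariant (duplicate ids, out-of-range values)."""


class ConfigError(UcsigError):
    """A configuration value is out of range or internally inconsistent."""


class UsageError(UcsigError):
    """An operation was called with incompatible inputs (e.g. mixed species)."""
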