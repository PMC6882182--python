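"""Exception hierarchy.

Errors split into three families so the CLI can map them to exit codes:
user/argument errors, data/format errors, and the privacy guard's hard stop.
"""


class VariomeError(Exception):
    """Base class for all package errors."""


class ArgumentError(VariomeError, ValueError):
    """Invalid argument supplied by the caller (exit code 1 at the CLI)."""


class ConfigError(VariomeError):
    """Malformed analysis configuration table."""


class FormatError(VariomeError):
    """Malformed input data: bad magic, truncated body, unparsable line."""


class CorruptionError(FormatError):
    """Data decoded but failed an integrity check (CRC mismatch)."""


class UnsupportedServerError(VariomeError):
    """Remote server does not honor HTTP Range requests."""


class PrivacyError(VariomeError):
    """An outbound payload contained sample-level genotype information."""
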