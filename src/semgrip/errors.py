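"""Exception hierarchy for semgrip.

All errors derive from :class:`SemgripError` so callers can catch the
package's failures with one clause; each subclass also derives from the
closest builtin (ValueError) so generic handling keeps working.
"""


class SemgripError(Exception):
    """Base class for all semgrip errors."""


class ProtocolError(SemgripError, ValueError):
    """Malformed packet stream or invalid protocol configuration."""


class FrameSyncError(ProtocolError):
    """Magic bytes at a frame boundary do not match the protocol."""


class PacketLengthError(ProtocolError):
    """A byte buffer is shorter than one serialized packet."""


class SampleRangeError(ProtocolError, ValueError):
    """An ADC code lies outside the converter's range."""


class StageError(SemgripError, ValueError):
    """A signal segment is at the wrong pipeline stage for an operation."""


class ConfigError(SemgripError, ValueError):
    """A configuration value violates its documented invariant."""
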