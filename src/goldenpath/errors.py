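"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`GoldenPathError`, so callers (and the CLI) can distinguish
user-facing problems from genuine bugs.
"""


class GoldenPathError(Exception):
    """Base class for all errors raised by goldenpath."""


class IntervalParseError(GoldenPathError, ValueError):
    """An interval string could not be parsed; the message names the bad part."""


class BinRangeError(GoldenPathError, ValueError):
    """A coordinate falls outside the range covered by the standard bin scheme."""


class TwoBitFormatError(GoldenPathError, ValueError):
    """A 2bit archive violates the format (bad magic, bad version, ...)."""


class TwoBitTruncationError(TwoBitFormatError):
    """A 2bit archive ended while a structure was still being read."""


class TwoBitEncodingError(GoldenPathError, ValueError):
    """A sequence handed to the 2bit writer contains an illegal character."""


class ConfigurationError(GoldenPathError, ValueError):
    """A connection locator or configuration value is unusable."""


class ConnectionFailedError(GoldenPathError, OSError):
    """A database file or server could not be reached."""


class UnknownTableError(GoldenPathError, KeyError):
    """The named table does not exist; the message lists available tables."""


class UnknownFieldError(GoldenPathError, KeyError):
    """A referenced column is not part of the reflected schema."""


class CapabilityError(GoldenPathError, TypeError):
    """The table lacks the columns an operation needs (e.g. positional columns)."""


class ValidationError(GoldenPathError, ValueError):
    """A record violates a structural invariant; the message names the field."""


class JoinerParseError(GoldenPathError, ValueError):
    """joiner schema text could not be parsed; the message carries the line number."""
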