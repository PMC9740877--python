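"""Exception hierarchy.

All errors raised by this package derive from :class:`TdgvError`, so callers
can catch one type at an application boundary. The subclasses distinguish
malformed files, invalid data values, bad configuration, calibration problems
and misuse of the API, matching the error contracts of the public functions.
"""


class TdgvError(Exception):
    """Base class for all errors raised by the tdgv package."""


class FormatError(TdgvError):
    """A file is structurally unreadable (missing columns, bad JSON shape)."""


class DataError(TdgvError):
    """File parsed, but the values violate an invariant (non-monotone time,
    overlapping segments, out-of-scale ratings, ...)."""


class ConfigError(TdgvError):
    """Invalid configuration (empty AOI list, non-positive rate, bad window)."""


class CalibrationError(TdgvError):
    """Threshold or baseline-quality calibration impossible on the given trace."""


class UsageError(TdgvError):
    """The API was called in an unsupported way (uncalibrated detector run,
    empty segment list, degenerate metric request)."""
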