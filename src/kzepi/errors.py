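"""Exception hierarchy.

Two broad families matter to callers: *validation* errors (bad parameters or
configuration, CLI exit code 2) and *data* errors (the inputs cannot support
the requested computation, CLI exit code 3).
"""


class KzepiError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(KzepiError, ValueError):
    """A parameter is outside its documented domain."""


class ConfigError(KzepiError, ValueError):
    """A configuration object failed validation; message lists the fields."""


class DataError(KzepiError):
    """Base class for errors caused by the data rather than the caller."""


class EmptyInputError(DataError):
    """An operation received no records/candidates to work with."""


class GapError(DataError):
    """A gap (missing month) was found where a gap-free series is required."""


class NonPositiveValueError(DataError):
    """Log transform hit a zero or negative value; message names the month."""


class InsufficientDataError(DataError):
    """Too few points for the requested fit."""


class InsufficientOverlapError(DataError):
    """Fewer than the minimum overlapping pairs at the requested lag."""


class NoOverlapError(DataError):
    """Two series share no common calendar span."""


class LeadTimeError(DataError):
    """The predictor series does not extend early enough for the lag."""


class CsvFormatError(DataError):
    """A CSV row failed to parse; message carries the line number."""
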