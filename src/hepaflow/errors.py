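"""Exception hierarchy for hepaflow.

Estimator failures mirror the failure modes a clinical device reports
("ERROR" instead of a number): they are raised as typed exceptions so
callers can distinguish *why* a channel produced no estimate.
"""


class HepaflowError(Exception):
    """Base class for all hepaflow errors."""


class TraceParseError(HepaflowError):
    """A trace file could not be parsed into a valid time series."""


class ConfigError(HepaflowError):
    """A configuration file failed validation."""


class NoInjectionError(HepaflowError):
    """No sustained departure from the pre-injection baseline was found."""


class RecirculationEndNotFoundError(HepaflowError):
    """No post-peak monotone decay was found (truncated or malformed record)."""


class InsufficientEliminationDataError(HepaflowError):
    """Fewer than the minimum number of usable elimination-phase samples."""


class DegenerateTraceError(HepaflowError):
    """A speckle record has zero variance; no autocorrelation is defined."""


class CorrelationTimeNotReachedError(HepaflowError):
    """The autocorrelation never fell to 1/e within the retained lag span."""


class UnderResolvedSamplingError(HepaflowError):
    """The expected correlation time spans too few samples at the given rate."""
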