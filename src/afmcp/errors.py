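"""Exception hierarchy for afmcp.

All package-specific failures derive from :class:`AfmcpError` so callers can
catch everything with one clause while batch drivers keep per-curve failures
non-fatal.
"""


class AfmcpError(Exception):
    """Base class for all afmcp errors."""


class FormatError(AfmcpError):
    """A curve file does not have the expected structure (columns, dialect)."""


class ParseError(FormatError):
    """A data row could not be parsed; the message names the line number."""


class MetadataError(FormatError):
    """Required acquisition metadata (spring constant, tip angle) is missing."""


class DegenerateSegmentError(AfmcpError):
    """A ramp segment is too short to be analysed."""


class DomainError(AfmcpError, ValueError):
    """A physical argument is outside the model's domain of validity."""


class DegenerateFitError(AfmcpError):
    """The fit target carries no signal (e.g. all-zero force)."""


class InsufficientDataError(AfmcpError):
    """Fewer valid points than the minimum the operation requires."""


class HeightUnavailableError(AfmcpError):
    """No glass reference position, so sample height cannot be computed."""


class SearchRangeError(AfmcpError):
    """No candidate contact point satisfies every component's edge margin."""


class CombinationError(AfmcpError):
    """Trace combination left no jointly valid candidate."""


class DetectionFailedError(AfmcpError):
    """The combined test parameter has no peak; no contact point reported."""


class UndefinedMetricError(AfmcpError):
    """A distribution metric is undefined for the given sample."""


class GenerationError(AfmcpError):
    """The synthetic force balance could not be solved (parameter pathology)."""


class NoPeakWarning(UserWarning):
    """A test-parameter trace was constant; normalization returned zeros."""
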