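"""Exception hierarchy for coenocycle.

All errors raised by the library derive from :class:`CoenocycleError` so
callers can catch package failures with a single except clause; the CLI maps
subclasses to distinct exit codes.
"""


class CoenocycleError(Exception):
    """Base class for all coenocycle errors."""


class InvalidInputError(CoenocycleError, ValueError):
    """An argument violates a documented precondition."""


class InvalidConfigError(CoenocycleError, ValueError):
    """An experiment or pipeline configuration violates its invariants."""


class CalibrationError(CoenocycleError):
    """No usable DNA-content peak could be found in a calibration sample."""


class EmptyHistogramError(CoenocycleError):
    """All events at a time point were flagged as debris."""


class NonGrowingSeriesError(CoenocycleError):
    """The fitted log2 DNA-content slope is not positive, so no doubling
    time is defined."""
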