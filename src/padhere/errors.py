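"""Exception types raised by the adherence pipeline."""


class PadhereError(Exception):
    """Base class for all package-specific errors."""


class OutOfScheduleError(PadhereError, ValueError):
    """A program week outside the goal-prescription window (weeks 3-24)."""


class ConfigurationError(PadhereError, ValueError):
    """An invalid schedule, simulation, or pipeline configuration."""


class MalformedRecordError(PadhereError, ValueError):
    """A daily record that violates the input contract (e.g. negative value)."""


class DuplicateRecordError(PadhereError, ValueError):
    """Duplicate (participant, week, day) keys in a daily log."""


class DataError(PadhereError, ValueError):
    """Inconsistent or incomplete analysis-stage data."""


class DegenerateFitError(PadhereError, ValueError):
    """A regression fit that is not identifiable (separation, one cluster)."""
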