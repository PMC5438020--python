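"""Exception hierarchy.

Every validation failure raises a subclass of :class:`DopakinError` so the
CLI can map any library error to a nonzero exit with a one-line message.
"""


class DopakinError(Exception):
    """Base class for all dopakin errors."""


class SpecificationError(DopakinError):
    """Invalid frame-schedule or simulation specification."""


class DomainError(DopakinError):
    """Argument outside the mathematical domain of an operation."""


class ScheduleError(DopakinError):
    """Mismatched or inconsistent frame schedules."""


class InsufficientDataError(DopakinError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(DopakinError):
    """Zero-variance or otherwise degenerate input to a statistic."""


class DegenerateReferenceError(DopakinError):
    """Reference-region curve unusable (zero/negative) in the fit window."""


class ConfigurationError(DopakinError):
    """Invalid cohort/run configuration."""


class IncompleteDesignError(DopakinError):
    """Missing scans or arms in a repeated-measures design."""


class SingularDesignError(DopakinError):
    """Rank-deficient design matrix in a regression."""


class FormatError(DopakinError):
    """Malformed input file (names the offending row/column)."""
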