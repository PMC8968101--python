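"""Exception hierarchy shared across the package."""


class MyoecvError(Exception):
    """Base class for all package-specific errors."""


class CohortParseError(MyoecvError):
    """A cohort CSV cell could not be parsed; names the offending row/column."""


class CohortValidationError(MyoecvError):
    """A cohort record violates a declared invariant (range, consistency)."""


class InsufficientDataError(MyoecvError):
    """Too few observations for the requested statistic."""


class NoEquilibriumError(MyoecvError):
    """No post-contrast window satisfied the ratio-stability criterion."""


class DegenerateFitError(MyoecvError):
    """A regression or correlation is undefined for the given inputs."""


class RoiError(MyoecvError):
    """Region-of-interest extraction refused or impossible."""
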