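"""Exception hierarchy shared across the toolkit."""


class GridEpiError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(GridEpiError, ValueError):
    """A scenario or analysis configuration violates its invariants."""


class InvalidCaseError(GridEpiError, ValueError):
    """A case history violates its invariants (e.g. birth after diagnosis)."""


class MissingDataError(GridEpiError, ValueError):
    """Required observations are absent (e.g. no residence inside a window)."""


class DataIntegrityError(GridEpiError, ValueError):
    """Cross-table consistency is broken (e.g. a cell with no unit mapping)."""


class UndefinedRateError(GridEpiError, ZeroDivisionError):
    """A rate or expectation is requested over an empty denominator."""


class ClassificationError(GridEpiError, ValueError):
    """Display classification is impossible (e.g. fewer than 5 units)."""


class InvalidExpectationError(GridEpiError, ValueError):
    """A scan-statistic expectation is degenerate (E <= 0 or E >= C)."""


class NoCasesError(GridEpiError, ValueError):
    """A scan was requested on a dataset with zero cases."""


class LegendError(GridEpiError, KeyError):
    """A raster code is absent from the configured land-cover legend."""


class EmptyZoneError(GridEpiError, ValueError):
    """A zonal query does not intersect the raster."""
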